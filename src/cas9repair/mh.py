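"""Microhomology-deletion kinetics: frequency vs inter-homology distance.

For every pure deletion using a microhomology of size s >= 2, the distance
between the ends of the two homologous copies is d = deletion size - s.
Mean outcome frequency per (s, d) bin is fit with an exponential decay
y_s = A * exp(B*d) for each microhomology size from 2 to 15 and each cell
line; amplitudes A are expected to grow with s and rates B to be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .io import ScreenDataset
from .outcomes import ClassifiedOutcome, Indel
from .profiling import classification_cache

__all__ = ["MHBin", "ExpFit", "tabulate_mh", "fit_exponential", "compare_fits"]

FIT_S_RANGE = range(2, 16)


@dataclass(frozen=True)
class MHBin:
    s: int
    d: int
    y: float  # mean fraction of mutated reads
    n: int  # contributing (target, outcome) observations


@dataclass
class ExpFit:
    s: int
    cell_line: str
    A: float
    B: float
    rss: float
    n_points: int
    converged: bool


def tabulate_mh(
    dataset: ScreenDataset,
    cell_line: str,
    cache: dict[tuple[str, Indel], ClassifiedOutcome] | None = None,
    min_mh: int = 2,
) -> list[MHBin]:
    """Mean frequency of microhomology deletions per (s, d) bin for one
    (pooled) cell line.  s is the capped MH length, d = size - s >= 0."""
    if cache is None:
        cache = classification_cache(dataset)
    obs: dict[tuple[int, int], list[float]] = {}
    for (key, tid), prof in dataset.profiles.items():
        if key.cell_line != cell_line:
            continue
        freqs = prof.frequencies()
        for o, f in freqs.items():
            if not o.is_deletion:
                continue
            co = cache[(tid, o)]
            if co.mh_len < min_mh:
                continue
            s, d = co.mh_len, o.deletion_size - co.mh_len
            assert d + s == o.deletion_size
            obs.setdefault((s, d), []).append(f)
    return [
        MHBin(s, d, float(np.mean(v)), len(v)) for (s, d), v in sorted(obs.items())
    ]


def fit_exponential(
    bins: list[MHBin],
    cell_line: str = "",
    min_points: int = 3,
    min_obs: int = 3,
) -> ExpFit | None:
    """Nonlinear least-squares fit of y = A*exp(B*d) to the bins of one
    microhomology size, initialized from a log-linear regression.

    Bins with fewer than ``min_obs`` observations are excluded; the fit
    requires >= ``min_points`` distinct distances.  Returns None when the
    data cannot support a fit; a non-converged fit carries NaN parameters."""
    if not bins:
        return None
    sizes = {b.s for b in bins}
    if len(sizes) != 1:
        raise ValueError("fit_exponential expects bins of a single MH size")
    s = sizes.pop()
    use = [b for b in bins if b.n >= min_obs]
    d = np.array([b.d for b in use], dtype=float)
    y = np.array([b.y for b in use], dtype=float)
    if len(np.unique(d)) < min_points:
        return None
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(d[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = (max(float(y.max()), 1e-6), -0.1)
    try:
        popt, _ = scipy.optimize.curve_fit(
            lambda dd, A, B: A * np.exp(B * dd), d, y, p0=p0, maxfev=10000
        )
        resid = y - popt[0] * np.exp(popt[1] * d)
        return ExpFit(s, cell_line, float(popt[0]), float(popt[1]),
                      float(resid @ resid), len(d), True)
    except RuntimeError:
        return ExpFit(s, cell_line, float("nan"), float("nan"), float("nan"),
                      len(d), False)


def fit_line(
    dataset: ScreenDataset,
    cell_line: str,
    cache: dict[tuple[str, Indel], ClassifiedOutcome] | None = None,
    s_range: range = FIT_S_RANGE,
    **fit_kwargs,
) -> list[ExpFit]:
    """All per-size exponential fits for one cell line."""
    bins = tabulate_mh(dataset, cell_line, cache=cache)
    fits = []
    for s in s_range:
        fit = fit_exponential([b for b in bins if b.s == s], cell_line, **fit_kwargs)
        if fit is not None:
            fits.append(fit)
    return fits


def compare_fits(fits_by_line: dict[str, list[ExpFit]]) -> tuple[pd.DataFrame, dict]:
    """Tabulate (line, s, A, B) and report, per line, whether amplitudes
    increase with microhomology size (Spearman rho) and whether every
    decay rate is negative."""
    rows = []
    report = {}
    for line, fits in sorted(fits_by_line.items()):
        ok = [f for f in fits if f.converged]
        for f in ok:
            rows.append((line, f.s, f.A, f.B, f.rss, f.n_points))
        if len(ok) >= 3:
            rho = scipy.stats.spearmanr([f.s for f in ok], [f.A for f in ok]).statistic
        else:
            rho = float("nan")
        report[line] = {
            "A_spearman_rho_vs_s": float(rho),
            "all_B_negative": bool(all(f.B < 0 for f in ok)) if ok else False,
            "n_fits": len(ok),
        }
    table = pd.DataFrame(rows, columns=["cell_line", "s", "A", "B", "rss", "n_points"])
    return table, report
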