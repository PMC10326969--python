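"""Screen filtering, pooling, frequency and fold-change analysis.

The processing order mirrors the screen's pipeline: guide profiles with
fewer than 100 mutated reads in any sample are removed, outcomes observed
in a single read across all samples are removed, and replicates and
timepoints are then pooled into one profile per (cell line, target).
Frequencies are fractions of mutated reads; fold changes are log2 ratios
of knockout to control frequency with a 0.1% pseudocount.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OutcomeProfile, SampleKey, ScreenDataset
from .outcomes import (
    ClassifiedOutcome,
    FlankMatch,
    Indel,
    OutcomeCategory,
    classify,
)

__all__ = [
    "LFCRecord",
    "filter_guides",
    "drop_singletons",
    "pool",
    "preprocess",
    "category_table",
    "lfc",
    "outcome_lfc",
    "profile_divergence",
    "insertion_report",
    "classification_cache",
]

logger = logging.getLogger(__name__)

LFC_PSEUDOCOUNT = 0.001  # 0.1% frequency pseudocount for all fold changes


@dataclass(frozen=True)
class LFCRecord:
    """Mean log2 fold change of one unit (category or outcome) in one line."""

    unit: str
    cell_line: str
    lfc: float
    pseudocount: float


def filter_guides(
    dataset: ScreenDataset, min_reads: int = 100
) -> tuple[ScreenDataset, dict[str, tuple[SampleKey, float]]]:
    """Drop targets whose profile in ANY sample has < ``min_reads`` mutated
    reads (a missing sample counts as zero).  Returns the filtered dataset
    and a log mapping removed target -> (offending sample, its reads)."""
    samples = dataset.sample_keys
    removed: dict[str, tuple[SampleKey, float]] = {}
    for tid in dataset.target_ids:
        for key in samples:
            prof = dataset.profiles.get((key, tid))
            total = prof.total_mutated if prof is not None else 0.0
            if total < min_reads:
                removed[tid] = (key, total)
                break
    kept = {tid: t for tid, t in dataset.targets.items() if tid not in removed}
    if not kept:
        logger.warning("filter_guides removed every target (min_reads=%d)", min_reads)
    profiles = {
        (key, tid): prof
        for (key, tid), prof in dataset.profiles.items()
        if tid in kept
    }
    return (
        ScreenDataset(kept, profiles, dataset.control_line_name),
        removed,
    )


def drop_singletons(dataset: ScreenDataset) -> ScreenDataset:
    """Remove outcomes whose summed count over all samples of a target is 1."""
    totals: dict[tuple[str, Indel], float] = {}
    for (key, tid), prof in dataset.profiles.items():
        for o, n in prof.counts.items():
            totals[(tid, o)] = totals.get((tid, o), 0.0) + n
    profiles = {}
    for (key, tid), prof in dataset.profiles.items():
        counts = {
            o: n for o, n in prof.counts.items() if totals[(tid, o)] != 1
        }
        profiles[(key, tid)] = OutcomeProfile(tid, counts)
    return ScreenDataset(dict(dataset.targets), profiles, dataset.control_line_name)


def pool(
    dataset: ScreenDataset, over: tuple[str, ...] = ("replicate", "timepoint")
) -> ScreenDataset:
    """Sum counts over the given SampleKey axes (replicates, timepoints).

    Pooled axes are re-labelled replicate=0 / timepoint="pooled"."""
    profiles: dict[tuple[SampleKey, str], OutcomeProfile] = {}
    for (key, tid), prof in dataset.profiles.items():
        new_key = SampleKey(
            key.cell_line,
            0 if "replicate" in over else key.replicate,
            "pooled" if "timepoint" in over else key.timepoint,
        )
        merged = profiles.setdefault((new_key, tid), OutcomeProfile(tid))
        for o, n in prof.counts.items():
            merged.counts[o] = merged.counts.get(o, 0) + n
    return ScreenDataset(dict(dataset.targets), profiles, dataset.control_line_name)


def preprocess(
    dataset: ScreenDataset, min_reads: int = 100
) -> tuple[ScreenDataset, dict]:
    """The full filtering/pooling pipeline in canonical order:
    filter_guides -> drop_singletons -> pool.  Returns the pooled dataset
    and a log of per-step counts."""
    filtered, removed = filter_guides(dataset, min_reads=min_reads)
    no_singletons = drop_singletons(filtered)
    pooled = pool(no_singletons)
    log = {
        "targets_in": len(dataset.targets),
        "targets_removed": len(removed),
        "removed_targets": removed,
        "targets_out": len(pooled.targets),
    }
    return pooled, log


def classification_cache(
    dataset: ScreenDataset, **classify_kwargs
) -> dict[tuple[str, Indel], ClassifiedOutcome]:
    """Classify every (target, outcome) pair once; shared by the tables."""
    cache: dict[tuple[str, Indel], ClassifiedOutcome] = {}
    for (key, tid), prof in dataset.profiles.items():
        target = dataset.targets[tid]
        for o in prof.counts:
            if (tid, o) not in cache:
                cache[(tid, o)] = classify(target, o, **classify_kwargs)
    return cache


def _category_freqs(
    prof: OutcomeProfile,
    tid: str,
    cache: dict[tuple[str, Indel], ClassifiedOutcome],
) -> dict[OutcomeCategory, float] | None:
    tot = prof.total_mutated
    if tot <= 0:
        return None
    out = {cat: 0.0 for cat in OutcomeCategory}
    for o, n in prof.counts.items():
        out[cache[(tid, o)].category] += n / tot
    return out


def category_table(
    dataset: ScreenDataset,
    cache: dict[tuple[str, Indel], ClassifiedOutcome] | None = None,
) -> pd.DataFrame:
    """Mean outcome-category frequency over targets, per cell line.

    Expects a pooled dataset (one profile per line and target); rows sum
    to 1.  Targets with zero mutated reads are excluded with a warning."""
    if cache is None:
        cache = classification_cache(dataset)
    rows: dict[str, list[dict[OutcomeCategory, float]]] = {}
    for (key, tid), prof in dataset.profiles.items():
        freqs = _category_freqs(prof, tid, cache)
        if freqs is None:
            logger.warning("target %s has no mutated reads in %s", tid, key.cell_line)
            continue
        rows.setdefault(key.cell_line, []).append(freqs)
    table = pd.DataFrame(
        {
            line: {
                cat.name: float(np.mean([f[cat] for f in per_target]))
                for cat in OutcomeCategory
            }
            for line, per_target in rows.items()
        }
    ).T
    return table.loc[sorted(table.index), [c.name for c in OutcomeCategory]]


def lfc(
    dataset: ScreenDataset,
    unit: str = "category",
    pseudocount: float = LFC_PSEUDOCOUNT,
    cache: dict[tuple[str, Indel], ClassifiedOutcome] | None = None,
) -> list[LFCRecord]:
    """Mean log2 fold change vs control, per unit and knockout line.

    unit="category": per target, log2((f_ko+eps)/(f_ctrl+eps)) for each of
    the ten categories, averaged over targets.  unit="outcome" averages
    per-outcome fold changes instead (see :func:`outcome_lfc` for the
    per-row matrix used in clustering)."""
    if unit not in ("category", "outcome"):
        raise ValueError(f"unknown unit {unit!r}")
    ctrl = dataset.control_line_name
    if ctrl not in dataset.cell_lines:
        raise ValueError(f"control line {ctrl!r} absent from dataset")
    if cache is None:
        cache = classification_cache(dataset)
    by_line: dict[str, dict[str, OutcomeProfile]] = {}
    for (key, tid), prof in dataset.profiles.items():
        by_line.setdefault(key.cell_line, {})[tid] = prof

    records = []
    for line in dataset.knockout_lines:
        acc: dict[str, list[float]] = {}
        for tid, ctrl_prof in by_line[ctrl].items():
            ko_prof = by_line.get(line, {}).get(tid)
            if ko_prof is None:
                continue
            if unit == "category":
                f_c = _category_freqs(ctrl_prof, tid, cache)
                f_k = _category_freqs(ko_prof, tid, cache)
                if f_c is None or f_k is None:
                    continue
                for cat in OutcomeCategory:
                    acc.setdefault(cat.name, []).append(
                        math.log2((f_k[cat] + pseudocount) / (f_c[cat] + pseudocount))
                    )
            else:
                fc = ctrl_prof.frequencies()
                fk = ko_prof.frequencies()
                for o in set(fc) | set(fk):
                    acc.setdefault(o.key(), []).append(
                        math.log2(
                            (fk.get(o, 0.0) + pseudocount)
                            / (fc.get(o, 0.0) + pseudocount)
                        )
                    )
        for unit_name, values in sorted(acc.items()):
            records.append(
                LFCRecord(unit_name, line, float(np.mean(values)), pseudocount)
            )
    return records


def outcome_lfc(
    dataset: ScreenDataset, pseudocount: float = LFC_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-(target, outcome) log2 fold change for every knockout line; the
    tidy long-format precursor of the clustering matrix."""
    ctrl = dataset.control_line_name
    by_line: dict[str, dict[str, OutcomeProfile]] = {}
    for (key, tid), prof in dataset.profiles.items():
        by_line.setdefault(key.cell_line, {})[tid] = prof
    if ctrl not in by_line:
        raise ValueError(f"control line {ctrl!r} absent from dataset")
    rows = []
    for tid, ctrl_prof in sorted(by_line[ctrl].items()):
        fc = ctrl_prof.frequencies()
        ko_freqs = {
            line: by_line[line][tid].frequencies()
            for line in by_line
            if line != ctrl and tid in by_line[line]
        }
        outcomes = set(fc)
        for f in ko_freqs.values():
            outcomes |= set(f)
        for o in sorted(outcomes, key=lambda x: x.key()):
            for line, f in ko_freqs.items():
                rows.append(
                    (
                        tid,
                        o.key(),
                        line,
                        math.log2(
                            (f.get(o, 0.0) + pseudocount) / (fc.get(o, 0.0) + pseudocount)
                        ),
                    )
                )
    return pd.DataFrame(rows, columns=["target_id", "outcome", "cell_line", "lfc"])


def profile_divergence(
    p: OutcomeProfile,
    q: OutcomeProfile,
    mode: str = "symmetric",
    pseudocount: float = 0.5,
) -> float:
    """KL divergence (bits) between two outcome profiles of one target.

    ``pseudocount`` reads are added to every outcome of the union support
    of both profiles before normalizing, guaranteeing finiteness even for
    disjoint supports.  mode="directed" gives D_KL(p||q); "symmetric"
    averages the two directions."""
    if p.target_id != q.target_id:
        raise ValueError("profiles compare only within one target")
    support = sorted(set(p.counts) | set(q.counts), key=lambda o: o.key())
    if not support:
        raise ValueError("both profiles are empty")
    cp = np.array([p.counts.get(o, 0.0) for o in support]) + pseudocount
    cq = np.array([q.counts.get(o, 0.0) for o in support]) + pseudocount
    if pseudocount == 0:
        keep = (cp > 0) | (cq > 0)
        cp, cq = cp[keep], cq[keep]
    fp, fq = cp / cp.sum(), cq / cq.sum()

    def d(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * (np.log2(a[mask]) - np.log2(b[mask]))))

    if mode == "directed":
        return d(fp, fq)
    if mode == "symmetric":
        return 0.5 * (d(fp, fq) + d(fq, fp))
    raise ValueError(f"unknown divergence mode {mode!r}")


def insertion_report(
    dataset: ScreenDataset,
    cache: dict[tuple[str, Indel], ClassifiedOutcome] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """1bp-insertion frequency and PAM-proximal fraction by flank pair.

    Per cell line and (distal, proximal) flank pair: the mean absolute
    1bp-insertion frequency over targets with that pair, and the proximal
    fraction PROX/(PROX+DIST) of 1bp-insertion reads over targets with
    differing flanks, with a seeded percentile bootstrap CI over targets."""
    if cache is None:
        cache = classification_cache(dataset)
    rng = np.random.default_rng(seed)
    per_target: dict[tuple[str, str, str], dict[str, tuple[float, float, float]]] = {}
    for (key, tid), prof in dataset.profiles.items():
        target = dataset.targets[tid]
        tot = prof.total_mutated
        if tot <= 0:
            continue
        f_any = f_prox = f_dist = 0.0
        for o, n in prof.counts.items():
            if not (o.is_insertion and o.insertion_size == 1):
                continue
            co = cache[(tid, o)]
            if co.flank_match is FlankMatch.NA:
                continue
            f_any += n / tot
            if co.flank_match is FlankMatch.PROXIMAL_ONLY:
                f_prox += n / tot
            elif co.flank_match is FlankMatch.DISTAL_ONLY:
                f_dist += n / tot
        per_target.setdefault(
            (key.cell_line, target.distal_flank, target.proximal_flank), {}
        )[tid] = (f_any, f_prox, f_dist)

    alpha = (1 - ci) / 2
    rows = []
    for (line, dl, pr), targets in sorted(per_target.items()):
        vals = np.array(list(targets.values()))
        n_t = len(vals)
        ins1 = float(vals[:, 0].mean())
        if dl != pr:
            denom = vals[:, 1].sum() + vals[:, 2].sum()
            prox_frac = float(vals[:, 1].sum() / denom) if denom > 0 else float("nan")
            boots = []
            if denom > 0:
                idx = rng.integers(0, n_t, size=(n_boot, n_t))
                bs = vals[idx]  # (n_boot, n_t, 3)
                bd = bs[:, :, 1].sum(axis=1) + bs[:, :, 2].sum(axis=1)
                with np.errstate(invalid="ignore"):
                    bf = bs[:, :, 1].sum(axis=1) / bd
                boots = bf[np.isfinite(bf)]
            if len(boots) > 0:
                lo, hi = np.quantile(boots, [alpha, 1 - alpha])
            else:
                lo = hi = float("nan")
        else:
            prox_frac = lo = hi = float("nan")
        rows.append((line, dl, pr, n_t, ins1, prox_frac, float(lo), float(hi)))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_line",
            "distal_flank",
            "proximal_flank",
            "n_targets",
            "ins1_frequency",
            "proximal_fraction",
            "ci_low",
            "ci_high",
        ],
    )
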