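"""Per-cell-line outcome-frequency predictor.

For each target, the candidate outcome space is every deletion of up to
30bp whose window spans (or touches) the cut plus every 1-2bp insertion
within 3bp of the cut.  Each candidate is described by binary features
(type, size, boundary offsets, microhomology, inserted sequence, flank
match, local nucleotide context, and declared pairwise products), and a
multinomial softmax model per cell line scores all candidates of a target
jointly.  Training minimizes the Kullback-Leibler divergence between the
measured profile (0.5 reads added to every candidate) and the softmax
prediction, summed over training targets, with an L2 penalty.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .io import OutcomeProfile, SampleKey, ScreenDataset
from .outcomes import (
    ClassifiedOutcome,
    FlankMatch,
    Indel,
    TargetSite,
    canonicalize,
    classify,
    insertion_at_cut,
)

__all__ = [
    "CandidateSet",
    "FeatureSchema",
    "ProfileModel",
    "EvalReport",
    "enumerate_candidates",
    "featurize",
    "map_observed",
    "build_design",
    "train",
    "predict",
    "evaluate",
    "replicate_divergence",
]

MAX_DELETION = 30
MAX_INSERTION = 2
INSERTION_RANGE = 3  # insertions within +-3bp of the cut

_BASES = "ACGT"
_MERS = [b for b in _BASES] + ["".join(p) for p in product(_BASES, repeat=2)]


@dataclass(frozen=True)
class CandidateSet:
    """Deduplicated canonical candidate outcomes for one target."""

    target_id: str
    candidates: tuple[Indel, ...]

    def index(self) -> dict[Indel, int]:
        return {c: i for i, c in enumerate(self.candidates)}


def enumerate_candidates(
    target: TargetSite, include_touching: bool = True
) -> CandidateSet:
    """Enumerate, canonicalize and deduplicate the candidate space.

    Pre-deduplication the space holds sum_{L=1..30}(L+1) = 495 deletions
    (windows with a <= c <= a+L) and 7 x 20 = 140 insertions.  With
    ``include_touching=False`` windows must strictly span the cut
    (a < c < a+L).
    """
    c = target.cut_index
    n = len(target.sequence)
    lo_margin, hi_margin = c, n - c
    need = MAX_DELETION + INSERTION_RANGE
    if lo_margin < need or hi_margin < need:
        raise ValueError(
            f"target {target.target_id!r} needs >= {need}bp of context on each "
            f"side of the cut (has {lo_margin}/{hi_margin})"
        )
    seen: dict[Indel, None] = {}
    for L in range(1, MAX_DELETION + 1):
        starts = range(c - L, c + 1) if include_touching else range(c - L + 1, c)
        for a in starts:
            seen.setdefault(canonicalize(target, Indel(a, a + L)), None)
    for pos in range(c - INSERTION_RANGE, c + INSERTION_RANGE + 1):
        for mer in _MERS:
            seen.setdefault(canonicalize(target, Indel(pos, pos, mer)), None)
    return CandidateSet(target.target_id, tuple(seen))


def _size_bin(size: int) -> str:
    if size <= 10:
        return str(size)
    if size <= 15:
        return "11-15"
    if size <= 20:
        return "16-20"
    return "21-30"


def _mh_bin(mh: int) -> str:
    return str(mh) if mh <= 15 else "16+"


class FeatureSchema:
    """Versioned binary feature schema over candidate outcomes.

    Families: outcome type; deletion size (one-hot 1..10 plus 11-15, 16-20,
    21-30 bins); left/right deletion boundary offsets from the cut (capped
    at 30); microhomology length (0..15, 16+); insertion length and
    inserted sequence identity; flank-match flags; nucleotide identity at
    six positions around the cut and at the two deletion junctions; and
    declared pairwise products.  Features constant within a target only
    influence predictions through their pairwise products (softmax is
    invariant to per-target constants).
    """

    version = "1"

    def __init__(
        self,
        pairwise: tuple[tuple[str, str], ...] = (
            ("del_size", "mh"),
            ("left_off", "right_off"),
            ("ins_seq", "flank"),
            ("ins_len", "ctx"),
            ("ins_seq", "ctx"),
        ),
    ):
        fam: dict[str, list[str]] = {}
        fam["type"] = ["type=DEL", "type=INS"]
        fam["del_size"] = [f"del_size={_size_bin(s)}" for s in [*range(1, 11), 11, 16, 21]]
        fam["left_off"] = [f"left_off={v}" for v in range(0, 31)]
        fam["right_off"] = [f"right_off={v}" for v in range(0, 31)]
        fam["mh"] = [f"mh={_mh_bin(v)}" for v in [*range(0, 16), 16]]
        fam["ins_len"] = ["ins_len=1", "ins_len=2"]
        fam["ins_seq"] = [f"ins_seq={m}" for m in _MERS]
        fam["flank"] = [f"flank={f.name}" for f in FlankMatch if f is not FlankMatch.NA]
        fam["ctx"] = [
            f"ctx[{off:+d}]={b}" for off in range(-3, 3) for b in _BASES
        ]
        fam["junction"] = [
            f"junction[{side}]={b}"
            for side in ("L-1", "L0", "R-1", "R0")
            for b in _BASES
        ]
        self.families = fam
        self.pairwise = pairwise
        names: list[str] = []
        for name in fam.values():
            names.extend(name)
        for fa, fb in pairwise:
            names.extend(f"{na}&{nb}" for na in fam[fa] for nb in fam[fb])
        self.feature_names: list[str] = names
        self._index = {name: i for i, name in enumerate(names)}

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def active_features(self, target: TargetSite, cand: Indel) -> list[int]:
        """Indices of features set for one candidate (all binary)."""
        seq = target.sequence
        c = target.cut_index
        co: ClassifiedOutcome = classify(target, cand)
        active: dict[str, list[str]] = {k: [] for k in self.families}
        if cand.is_deletion:
            active["type"] = ["type=DEL"]
            active["del_size"] = [f"del_size={_size_bin(cand.deletion_size)}"]
            active["left_off"] = [f"left_off={min(max(c - cand.start, 0), 30)}"]
            active["right_off"] = [f"right_off={min(max(cand.end - c, 0), 30)}"]
            active["mh"] = [f"mh={_mh_bin(co.mh_len)}"]
            junc = {
                "L-1": seq[cand.start - 1] if cand.start > 0 else None,
                "L0": seq[cand.start],
                "R-1": seq[cand.end - 1],
                "R0": seq[cand.end] if cand.end < len(seq) else None,
            }
            active["junction"] = [
                f"junction[{side}]={b}" for side, b in junc.items() if b is not None
            ]
        elif cand.is_insertion:
            placed = insertion_at_cut(target, cand) or cand.insert
            active["type"] = ["type=INS"]
            active["ins_len"] = [f"ins_len={len(cand.insert)}"]
            if len(placed) <= 2:
                active["ins_seq"] = [f"ins_seq={placed}"]
            if co.flank_match is not FlankMatch.NA:
                active["flank"] = [f"flank={co.flank_match.name}"]
        active["ctx"] = [
            f"ctx[{off:+d}]={seq[c + off]}"
            for off in range(-3, 3)
            if 0 <= c + off < len(seq)
        ]
        names = [n for group in active.values() for n in group]
        for fa, fb in self.pairwise:
            names.extend(
                f"{na}&{nb}" for na in active[fa] for nb in active[fb]
            )
        return [self._index[n] for n in names]


def featurize(
    target: TargetSite, candidates: CandidateSet, schema: FeatureSchema
) -> sp.csr_matrix:
    """Binary feature matrix, rows aligned with ``candidates.candidates``."""
    indptr = [0]
    indices: list[int] = []
    for cand in candidates.candidates:
        cols = schema.active_features(target, cand)
        indices.extend(sorted(cols))
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.float64)
    return sp.csr_matrix(
        (data, np.asarray(indices), np.asarray(indptr)),
        shape=(len(candidates.candidates), schema.n_features),
    )


def map_observed(
    profile: OutcomeProfile, candidates: CandidateSet
) -> tuple[np.ndarray, float]:
    """Align observed counts to the candidate index.

    Outcomes outside the candidate space (e.g. compound indels) are dropped;
    the dropped read fraction is returned alongside the aligned vector.
    """
    idx = candidates.index()
    counts = np.zeros(len(candidates.candidates))
    dropped = 0.0
    for outcome, n in profile.counts.items():
        j = idx.get(outcome)
        if j is None:
            dropped += n
        else:
            counts[j] += n
    total = profile.total_mutated
    frac = dropped / total if total > 0 else 0.0
    return counts, frac


@dataclass
class ProfileModel:
    """Softmax outcome-frequency model for one cell line."""

    cell_line: str
    weights: np.ndarray
    feature_names: list[str]
    schema_version: str
    lam: float
    seed: int
    n_iter: int
    final_loss_bits: float
    converged: bool


@dataclass
class SplitRecord:
    train_targets: list[str]
    test_targets: list[str]
    seed: int
    test_frac: float


@dataclass
class EvalReport:
    """Held-out performance at three levels of aggregation."""

    cell_line: str
    per_target_divergence: dict[str, float]
    r_outcomes: float
    r_categories: float
    r_inframe: float
    test_targets: list[str]
    mean_dropped_fraction: float
    inframe_measured: dict[str, float]
    inframe_predicted: dict[str, float]

    @property
    def mean_divergence(self) -> float:
        return float(np.mean(list(self.per_target_divergence.values())))


def build_design(
    targets: dict[str, TargetSite],
    schema: FeatureSchema,
    include_touching: bool = True,
) -> dict[str, tuple[CandidateSet, sp.csr_matrix]]:
    """Candidate sets + feature matrices, computed once and shared across
    the per-line models (featurization does not depend on the line)."""
    design = {}
    for tid, t in sorted(targets.items()):
        cands = enumerate_candidates(t, include_touching=include_touching)
        design[tid] = (cands, featurize(t, cands, schema))
    return design


def _segment_softmax(scores: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Softmax within contiguous row segments delimited by ``starts``."""
    shifted = scores - np.repeat(np.maximum.reduceat(scores, starts), np.diff(np.append(starts, len(scores))))
    ex = np.exp(shifted)
    z = np.add.reduceat(ex, starts)
    return ex / np.repeat(z, np.diff(np.append(starts, len(scores))))


def train(
    dataset: ScreenDataset,
    cell_line: str,
    schema: FeatureSchema | None = None,
    lam: float = 1e-3,
    seed: int = 0,
    test_frac: float = 0.1,
    pseudocount: float = 0.5,
    design: dict[str, tuple[CandidateSet, sp.csr_matrix]] | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> tuple[ProfileModel, SplitRecord]:
    """Fit the softmax profile model for one cell line.

    The dataset must be pooled to one profile per (line, target).  Targets
    are split at the target level; ``test_frac`` of them are held out.  The
    loss is sum_t KL(m_t || p_t) + lam * ||w||^2 with m_t the pseudocounted
    measured frequencies and p_t the softmax prediction.
    """
    if schema is None:
        schema = FeatureSchema()
    line_profiles = {
        tid: prof
        for (key, tid), prof in dataset.profiles.items()
        if key.cell_line == cell_line
    }
    if not line_profiles:
        raise ValueError(f"no profiles for cell line {cell_line!r}")
    tids = sorted(line_profiles)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(tids))
    n_test = int(round(test_frac * len(tids)))
    test_targets = sorted(order[:n_test])
    train_targets = sorted(order[n_test:])
    if not train_targets:
        raise ValueError("empty training set")
    if design is None:
        design = build_design(
            {tid: dataset.targets[tid] for tid in tids}, schema
        )

    blocks, m_parts, starts = [], [], [0]
    for tid in train_targets:
        cands, X = design[tid]
        counts, _ = map_observed(line_profiles[tid], cands)
        m = counts + pseudocount
        m_parts.append(m / m.sum())
        blocks.append(X)
        starts.append(starts[-1] + X.shape[0])
    X_all = sp.vstack(blocks, format="csr")
    m_all = np.concatenate(m_parts)
    seg_starts = np.asarray(starts[:-1])
    entropy_term = float(np.sum(m_all * np.log(m_all)))  # sum_t sum_j m log m

    n_evals = [0]

    def loss_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        n_evals[0] += 1
        scores = X_all @ w
        p = _segment_softmax(scores, seg_starts)
        loss = entropy_term - float(np.sum(m_all * np.log(p))) + lam * float(w @ w)
        grad = X_all.T @ (p - m_all) + 2.0 * lam * w
        return loss, grad

    w0 = np.zeros(schema.n_features)
    res = scipy.optimize.minimize(
        loss_grad,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError("non-finite training loss; check inputs")
    model = ProfileModel(
        cell_line=cell_line,
        weights=np.asarray(res.x),
        feature_names=schema.feature_names,
        schema_version=schema.version,
        lam=lam,
        seed=seed,
        n_iter=int(res.nit),
        final_loss_bits=float(res.fun - lam * res.x @ res.x)
        / np.log(2)
        / max(len(train_targets), 1),
        converged=bool(res.success),
    )
    return model, SplitRecord(train_targets, test_targets, seed, test_frac)


def predict(
    model: ProfileModel,
    target: TargetSite,
    schema: FeatureSchema | None = None,
    design_entry: tuple[CandidateSet, sp.csr_matrix] | None = None,
) -> tuple[CandidateSet, np.ndarray]:
    """Predicted frequencies over the candidate set of one target (sum 1)."""
    if design_entry is None:
        if schema is None:
            schema = FeatureSchema()
        cands = enumerate_candidates(target)
        X = featurize(target, cands, schema)
    else:
        cands, X = design_entry
    scores = X @ model.weights
    scores = scores - scores.max()
    p = np.exp(scores)
    p /= p.sum()
    return cands, p


def _kl_bits(m: np.ndarray, p: np.ndarray, mode: str) -> float:
    def d(a, b):
        return float(np.sum(a * (np.log2(a) - np.log2(b))))

    if mode == "directed":
        return d(m, p)
    if mode == "symmetric":
        return 0.5 * (d(m, p) + d(p, m))
    raise ValueError(f"unknown divergence mode {mode!r}")


def evaluate(
    model: ProfileModel,
    dataset: ScreenDataset,
    test_targets: list[str],
    schema: FeatureSchema | None = None,
    design: dict[str, tuple[CandidateSet, sp.csr_matrix]] | None = None,
    pseudocount: float = 0.5,
    mode: str = "directed",
    cell_line: str | None = None,
) -> EvalReport:
    """Held-out evaluation: per-target KL divergence (bits) plus Pearson r
    for individual outcomes, outcome categories, and in-frame fraction.

    ``cell_line`` overrides the line whose measured profiles are compared
    against (e.g. scoring a control-trained model on knockout data)."""
    if not test_targets:
        raise ValueError("empty test set")
    if schema is None:
        schema = FeatureSchema()
    line = cell_line if cell_line is not None else model.cell_line
    divergences: dict[str, float] = {}
    meas_out, pred_out = [], []
    meas_cat, pred_cat = [], []
    meas_if, pred_if = {}, {}
    dropped_fracs = []
    for tid in sorted(test_targets):
        prof = dataset.profiles.get((_line_key(dataset, line), tid))
        if prof is None:
            raise ValueError(f"no pooled profile for ({line!r}, {tid!r})")
        target = dataset.targets[tid]
        entry = design[tid] if design is not None else None
        cands, p = predict(model, target, schema=schema, design_entry=entry)
        counts, frac = map_observed(prof, cands)
        dropped_fracs.append(frac)
        m = counts + pseudocount
        m = m / m.sum()
        divergences[tid] = _kl_bits(m, p, mode)
        meas_out.extend(m)
        pred_out.extend(p)
        cats = [classify(target, cand).category for cand in cands.candidates]
        inframe = np.array(
            [cand.net_change % 3 == 0 for cand in cands.candidates], dtype=bool
        )
        for cat in {c for c in cats}:
            mask = np.array([c is cat for c in cats])
            meas_cat.append(float(m[mask].sum()))
            pred_cat.append(float(p[mask].sum()))
        meas_if[tid] = float(m[inframe].sum())
        pred_if[tid] = float(p[inframe].sum())

    def r(x, y):
        x, y = np.asarray(x), np.asarray(y)
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    return EvalReport(
        cell_line=line,
        per_target_divergence=divergences,
        r_outcomes=r(meas_out, pred_out),
        r_categories=r(meas_cat, pred_cat),
        r_inframe=r(list(meas_if.values()), list(pred_if.values())),
        test_targets=sorted(test_targets),
        mean_dropped_fraction=float(np.mean(dropped_fracs)),
        inframe_measured=meas_if,
        inframe_predicted=pred_if,
    )


def _line_key(dataset: ScreenDataset, cell_line: str) -> SampleKey:
    keys = {key for key, _ in dataset.profiles if key.cell_line == cell_line}
    if len(keys) != 1:
        raise ValueError(
            f"expected one pooled sample for line {cell_line!r}, found {len(keys)}"
        )
    return keys.pop()


def replicate_divergence(
    unpooled: ScreenDataset,
    cell_line: str,
    targets: list[str] | None = None,
    pseudocount: float = 0.5,
    mode: str = "symmetric",
) -> dict[str, float]:
    """KL divergence between the replicate profiles of each target, the
    experimental reproducibility baseline for model divergences."""
    from .profiling import pool, profile_divergence

    by_rep = pool(unpooled, over=("timepoint",))
    keys = sorted({key for key, _ in by_rep.profiles if key.cell_line == cell_line})
    if len(keys) < 2:
        raise ValueError(f"need >= 2 replicates for line {cell_line!r}")
    k1, k2 = keys[:2]
    out: dict[str, float] = {}
    tids = targets if targets is not None else sorted(unpooled.targets)
    for tid in tids:
        p1 = by_rep.profiles.get((k1, tid))
        p2 = by_rep.profiles.get((k2, tid))
        if p1 is None or p2 is None:
            continue
        out[tid] = profile_divergence(p1, p2, mode=mode, pseudocount=pseudocount)
    return out
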