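"""Synthetic knockout-screen generator with exported ground truth.

Emulates the statistical structure the analyses assume: a library of
targets (random protospacers with an NGG PAM in a fixed shared context),
a per-target generative outcome distribution in control cells, and
knockout lines whose category weights are shifted multiplicatively on the
log2 scale before renormalization.  Read counts are multinomial draws at
log-normally distributed per-sample depth.

The control distribution encodes the features the analyses look for:
microhomology-mediated deletions weighted A_s * exp(B*d) with amplitude
A_s = alpha * exp(gamma*s) growing with microhomology size s and decaying
with inter-homology distance d; non-homologous deletions with a sharply
size-decaying plus flat background; 1bp insertions with flank-dependent
propensities (PAM-distal T/A targets roughly three times as
insertion-prone as G/C ones, and a mostly-distal match bias); small
weights for 2bp duplications and a compound insertion-deletion tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import OutcomeProfile, SampleKey, ScreenDataset
from .outcomes import (
    Indel,
    OutcomeCategory,
    TargetSite,
    canonicalize,
    classify,
    insertion_at_cut,
)
from .predictor import enumerate_candidates

__all__ = [
    "GenerativeParams",
    "GroundTruth",
    "DEFAULT_EFFECTS",
    "archetype_effects",
    "generate_targets",
    "control_distribution",
    "apply_effects",
    "sample_screen",
    "dataset_from_truth",
]

# Fixed shared flanking context (invariant across targets, as in a screen
# where constructs share a vector backbone).  Long enough for the 33bp of
# context each side of the cut that candidate enumeration requires.
LEFT_CONTEXT = "AGCTGACTCGGTACCTTAGGACCGGTCAATTGCTAGCTAG"
RIGHT_CONTEXT = "CATGGTCCTGCTGGAGTTCGTGACCGCCGCCGGGATCACT"


@dataclass
class GenerativeParams:
    """Tunable laws of the generator; defaults emulate the screen's scale
    and the control-cell outcome composition."""

    n_targets: int = 2838
    protospacer_len: int = 20
    # depth model: log-normal mutated reads per (sample, target)
    depth_median: float = 1000.0
    depth_log_sd: float = 0.3
    replicates: int = 2
    timepoints: tuple[str, ...] = ("d7", "d14")
    # MH-deletion law: weight = min(alpha*exp(gamma*s), a_cap) * exp(B*d)
    mh_alpha: float = 0.0085
    mh_gamma: float = 0.45
    mh_a_cap: float = 0.25
    mh_decay_B: float = -0.12
    # non-homologous deletion background: bg1*exp(-size/tau1) + bg0
    del_bg1: float = 0.016
    del_tau1: float = 1.5
    del_bg0: float = 5e-5
    mh1_boost: float = 2.0
    # 1bp insertions: total weight per target scales with the PAM-distal
    # flank (T/A ~3x G/C); the proximal share follows base propensities.
    ins1_scale: float = 0.023
    ins1_distal_ta_ratio: float = 3.0
    ins_base_propensity: dict[str, float] = field(
        default_factory=lambda: {"T": 0.45, "A": 0.30, "C": 0.17, "G": 0.08}
    )
    ins1_distal_boost: float = 4.0
    ins1_neither_w: float = 5e-5
    ins2_dup_w: float = 0.004
    ins2_other_w: float = 2e-5
    ins_offcut_w: float = 2e-5
    # compound insertion-deletion tail
    compound_total_w: float = 0.02
    n_compound: int = 3


# Directions follow the reported knockout phenotypes: NHEJ knockouts
# (Lig4/Xrcc5/Xlf) deplete small indels and cut-site insertions while long
# deletions rise; Nbn suppresses all 3bp+ deletions; Polq depletes medium
# MH deletions and increases long non-MH ones; Prkdc and Polm deplete
# PAM-proximal insertions specifically.  Magnitudes are package defaults.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "control": {},
    "Lig4": {"I12_DIST": -5.0, "I12_PROX": -2.0, "D1": -2.0, "D2": -1.0,
             "D3_9_MH": 0.5, "D10P_MH": 0.5, "D10P": 0.5},
    "Xrcc5": {"I12_DIST": -3.1, "I12_PROX": -4.2, "D1": -1.5, "D10P": 1.0,
              "D10P_MH": 0.5},
    "Xlf": {"I12_DIST": -2.0, "I12_PROX": -2.0, "D1": -1.5, "D3_9_MH": 0.3,
            "D10P_MH": 0.4},
    "Prkdc": {"I12_PROX": -2.3, "I12_DIST": -0.3},
    "Polm": {"I12_PROX": -1.5, "I12_DIST": -0.3},
    "Poll": {"I12_DIST": -1.0, "I12_PROX": -1.0},
    "Nbn": {"D3_9_MH": -2.0, "D3_9": -2.0, "D10P_MH": -2.5, "D10P": -2.0,
            "I12_DIST": 1.2, "I12_PROX": 1.0, "D1": 1.2},
    "Polq": {"D3_9_MH": -1.6, "D3_9": -0.5, "D10P": 1.8, "D10P_MH": 0.3,
             "I12_DIST": 0.5},
    "Lig1": {}, "Lig3": {}, "Parp1": {}, "Dclre1c": {}, "Wrn": {},
    "Trex1": {}, "Trp53": {}, "Trp53bp1": {}, "Rad52": {}, "Ercc1": {},
}


def archetype_effects(magnitude: float = 4.0) -> dict[str, dict[str, float]]:
    """Effect spec planting three clean response archetypes, used by the
    clustering recovery analyses: NHEJ-sensitive small indels, MMEJ-
    sensitive 3bp+ deletions, and Prkdc/Polm-sensitive proximal insertions."""
    m = -abs(magnitude)
    eff = {line: {} for line in DEFAULT_EFFECTS}
    for line in ("Lig4", "Xrcc5", "Xlf"):
        eff[line] = {"D1": m, "D2": m, "I12_DIST": m}
    for line in ("Nbn", "Polq"):
        eff[line] = {"D3_9_MH": m, "D3_9": m, "D10P_MH": m, "D10P": m}
    for line in ("Prkdc", "Polm"):
        eff[line] = {"I12_PROX": m}
    return eff


def generate_targets(
    params: GenerativeParams, seed: int = 0
) -> dict[str, TargetSite]:
    """Random protospacers with a forced NGG PAM, embedded in the shared
    context.  Deterministic under ``seed``."""
    if params.n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    targets: dict[str, TargetSite] = {}
    width = len(str(params.n_targets - 1))
    for i in range(params.n_targets):
        proto = "".join(rng.choice(bases, size=params.protospacer_len))
        pam = rng.choice(bases) + "GG"
        seq = LEFT_CONTEXT + proto + pam + RIGHT_CONTEXT
        tid = f"T{i:0{width}d}"
        targets[tid] = TargetSite(
            target_id=tid,
            sequence=seq,
            protospacer_start=len(LEFT_CONTEXT),
            pam_start=len(LEFT_CONTEXT) + params.protospacer_len,
        )
    return targets


def _compound_tail(target: TargetSite, params: GenerativeParams) -> list[Indel]:
    """Deterministic compound insertion-deletion outcomes near the cut,
    constructed to remain compound under canonicalization."""
    seq = target.sequence
    c = target.cut_index
    out = []
    for j in range(params.n_compound):
        a, b = c - 2 - j, c + 1 + j
        first = next(x for x in "ACGT" if x != seq[a])
        last = next(x for x in "ACGT" if x != seq[b - 1])
        out.append(canonicalize(target, Indel(a, b, first + last)))
    return out


def control_distribution(
    target: TargetSite, params: GenerativeParams
) -> dict[Indel, float]:
    """Generative outcome probabilities for one target in control cells.

    Support is the candidate space of the predictor plus the compound
    tail; weights follow the laws described in the module docstring and
    normalize to 1."""
    seq = target.sequence
    c = target.cut_index
    dl, pr = target.distal_flank, target.proximal_flank
    p = params

    prop = p.ins_base_propensity
    w_pair = p.ins1_scale * (p.ins1_distal_ta_ratio if dl in "TA" else 1.0)
    if dl == pr:
        prox_frac = 0.0
    else:
        prox_frac = prop[pr] / (prop[pr] + p.ins1_distal_boost * prop[dl])

    weights: dict[Indel, float] = {}
    for cand in enumerate_candidates(target).candidates:
        if cand.is_deletion:
            co = classify(target, cand)
            s, size = co.mh_len, cand.deletion_size
            if s >= 2:
                a_s = min(p.mh_alpha * math.exp(p.mh_gamma * s), p.mh_a_cap)
                w = a_s * math.exp(p.mh_decay_B * (size - s))
            else:
                w = p.del_bg1 * math.exp(-size / p.del_tau1) + p.del_bg0
                if s == 1:
                    w *= p.mh1_boost
        else:
            placed = insertion_at_cut(target, cand)
            if placed is None:
                w = p.ins_offcut_w
            elif len(placed) == 1:
                if placed == dl:
                    w = w_pair * (1.0 - prox_frac) if dl != pr else w_pair
                elif placed == pr:
                    w = w_pair * prox_frac
                else:
                    w = p.ins1_neither_w
            else:  # 2bp cut-site insertion
                w = p.ins2_dup_w if placed == seq[c - 2 : c] else p.ins2_other_w
        weights[cand] = weights.get(cand, 0.0) + w

    tail = _compound_tail(target, params)
    if tail:
        w_each = p.compound_total_w / len(tail)
        for cand in tail:
            weights[cand] = weights.get(cand, 0.0) + w_each

    total = sum(weights.values())
    if total <= 0:
        raise ValueError("degenerate all-zero generative distribution")
    return {o: w / total for o, w in weights.items()}


def apply_effects(
    dist: dict[Indel, float],
    target: TargetSite,
    effects: dict[str, float],
) -> dict[Indel, float]:
    """Shift category weights by 2**lfc and renormalize."""
    if not effects:
        return dict(dist)
    out = {}
    for o, w in dist.items():
        cat = classify(target, o).category
        out[o] = w * 2.0 ** effects.get(cat.name, 0.0)
    total = sum(out.values())
    return {o: w / total for o, w in out.items()}


@dataclass
class GroundTruth:
    """Exact generative state of a sampled screen, for recovery tests."""

    probabilities: dict[tuple[str, str], tuple[tuple[Indel, ...], np.ndarray]]
    effects: dict[str, dict[str, float]]
    params: GenerativeParams

    def distribution(self, cell_line: str, target_id: str) -> dict[Indel, float]:
        outcomes, probs = self.probabilities[(cell_line, target_id)]
        return dict(zip(outcomes, probs))

    def realized_category_lfc(
        self,
        targets: dict[str, TargetSite],
        cell_line: str,
        pseudocount: float = 0.001,
        control_line: str = "control",
    ) -> dict[str, float]:
        """Post-renormalization category fold changes the screen actually
        encodes (they differ from the nominal effect spec because
        frequencies are compositional)."""
        acc: dict[str, list[float]] = {c.name: [] for c in OutcomeCategory}
        tids = sorted({tid for (line, tid) in self.probabilities if line == cell_line})
        for tid in tids:
            target = targets[tid]
            f_ko = {c.name: 0.0 for c in OutcomeCategory}
            f_ctrl = {c.name: 0.0 for c in OutcomeCategory}
            for o, w in self.distribution(cell_line, tid).items():
                f_ko[classify(target, o).category.name] += w
            for o, w in self.distribution(control_line, tid).items():
                f_ctrl[classify(target, o).category.name] += w
            for name in f_ko:
                acc[name].append(
                    math.log2((f_ko[name] + pseudocount) / (f_ctrl[name] + pseudocount))
                )
        return {name: float(np.mean(v)) for name, v in acc.items()}

    def realized_mh_fits(self, targets: dict[str, TargetSite], cell_line: str = "control"):
        """Exponential MH-decay fits on the exact generative probabilities.

        Because frequencies are compositional, the decay rate a screen
        actually encodes differs slightly from the nominal ``mh_decay_B``
        (each outcome's weight also feeds its target's normalizer); this
        is the realized law, the recovery target for estimators."""
        from .mh import fit_line

        exact = dataset_from_truth(
            self, targets, lines=[cell_line], control_line=cell_line
        )
        return fit_line(exact, cell_line)


def sample_screen(
    targets: dict[str, TargetSite],
    params: GenerativeParams,
    effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    lines: list[str] | None = None,
    control_line: str = "control",
) -> tuple[ScreenDataset, GroundTruth]:
    """Draw a full read-count screen plus its generative ground truth.

    For every (line, replicate, timepoint, target), the mutated-read depth
    is log-normal and outcome counts are multinomial from the effect-
    adjusted distribution.  Timepoints are i.i.d. (no drift).  Identical
    seeds give identical counts."""
    if effects is None:
        effects = DEFAULT_EFFECTS
    if control_line not in effects:
        raise ValueError(f"effects must include the control line {control_line!r}")
    if effects.get(control_line):
        raise ValueError("control line must have all-zero effects")
    if lines is None:
        lines = sorted(effects)
    rng = np.random.default_rng(seed)
    profiles: dict[tuple[SampleKey, str], OutcomeProfile] = {}
    truth_probs: dict[tuple[str, str], tuple[tuple[Indel, ...], np.ndarray]] = {}
    for tid, target in sorted(targets.items()):
        base = control_distribution(target, params)
        for line in lines:
            dist = apply_effects(base, target, effects.get(line, {}))
            outcomes = tuple(dist)
            probs = np.array([dist[o] for o in outcomes])
            truth_probs[(line, tid)] = (outcomes, probs)
            for rep in range(1, params.replicates + 1):
                for tp in params.timepoints:
                    depth = int(
                        round(
                            float(
                                rng.lognormal(
                                    math.log(params.depth_median), params.depth_log_sd
                                )
                            )
                        )
                    )
                    counts = rng.multinomial(max(depth, 1), probs)
                    key = SampleKey(line, rep, tp)
                    profiles[(key, tid)] = OutcomeProfile(
                        tid,
                        {o: int(n) for o, n in zip(outcomes, counts) if n > 0},
                    )
    dataset = ScreenDataset(dict(targets), profiles, control_line)
    return dataset, GroundTruth(truth_probs, dict(effects), params)


def dataset_from_truth(
    truth: GroundTruth,
    targets: dict[str, TargetSite],
    lines: list[str] | None = None,
    control_line: str = "control",
) -> ScreenDataset:
    """Infinite-depth screen: profiles whose 'counts' are the exact
    generative probabilities (total_mutated == 1 per profile)."""
    if lines is None:
        lines = sorted({line for line, _ in truth.probabilities})
    profiles = {}
    for (line, tid), (outcomes, probs) in truth.probabilities.items():
        if line not in lines:
            continue
        key = SampleKey(line, 0, "exact")
        profiles[(key, tid)] = OutcomeProfile(
            tid, {o: float(w) for o, w in zip(outcomes, probs)}
        )
    return ScreenDataset(dict(targets), profiles, control_line)
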