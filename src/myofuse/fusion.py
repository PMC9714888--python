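"""Dempster-Shafer decision-level fusion of the sEMG and ECG classifiers.

Each modality's softmax output is turned into a basic probability
assignment (BPA) by credibility discounting: a modality with credibility c
keeps mass c * p_i on each singleton state and parks the remaining 1 - c
on the full frame Theta (ignorance).  The two bodies of evidence are then
merged with Dempster's rule — conflict-normalised products over focal-set
intersections — and the fused decision is the singleton with the largest
combined mass.  Default credibilities are sEMG 0.591 / ECG 0.409, the
cross-validated reliabilities of the two modality classifiers; they can be
re-estimated from accuracies by simple normalisation (the pair sums to 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .states import FRAME, STATES
from .tcn import StateProbabilities

__all__ = [
    "MassFunction",
    "CredibilityWeights",
    "DEFAULT_CREDIBILITY",
    "make_bpa",
    "dempster_combine",
    "fuse_decision",
    "estimate_credibility",
    "fuse_probabilities",
]

_TOL = 1e-9
_CONFLICT_TOL = 1e-12

SINGLETONS = tuple(frozenset({s}) for s in STATES)
FOCAL_ELEMENTS = SINGLETONS + (FRAME,)


@dataclass
class MassFunction:
    """A BPA over the fatigue frame: three singletons plus Theta.

    Masses are non-negative and sum to 1; the empty set carries no mass by
    construction.
    """

    masses: dict[frozenset, float]

    def __post_init__(self) -> None:
        clean = {}
        for focal, m in self.masses.items():
            focal = frozenset(focal)
            if not focal or not focal <= FRAME:
                raise ValueError(f"focal element {set(focal)} outside the frame")
            if m < -_TOL:
                raise ValueError(f"negative mass {m} on {set(focal)}")
            if m > 0 or focal in FOCAL_ELEMENTS:
                clean[focal] = float(max(m, 0.0))
        total = sum(clean.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"masses sum to {total}, expected 1")
        self.masses = clean

    def __getitem__(self, focal) -> float:
        return self.masses.get(frozenset(focal), 0.0)

    @property
    def theta(self) -> float:
        return self[FRAME]

    def singleton_masses(self) -> dict[int, float]:
        return {s: self[{s}] for s in STATES}


@dataclass
class CredibilityWeights:
    """Per-modality reliabilities used to discount the softmax evidence."""

    c_semg: float = 0.591
    c_ecg: float = 0.409

    def __post_init__(self) -> None:
        for name in ("c_semg", "c_ecg"):
            c = getattr(self, name)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {c}")


DEFAULT_CREDIBILITY = CredibilityWeights()


def make_bpa(p: StateProbabilities, credibility: float) -> MassFunction:
    """Credibility-discounted BPA: m({s}) = c * p_s, m(Theta) = 1 - c."""
    if not 0.0 <= credibility <= 1.0:
        raise ValueError(f"credibility must lie in [0, 1], got {credibility}")
    masses: dict[frozenset, float] = {
        frozenset({s}): credibility * p.p[s] for s in STATES
    }
    masses[FRAME] = 1.0 - credibility
    return MassFunction(masses)


def dempster_combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule: conflict-normalised intersection products.

    ``m(A) = sum_{B ^ C = A} m1(B) m2(C) / (1 - K)`` with conflict
    ``K = sum_{B ^ C = empty} m1(B) m2(C)``.  Total conflict (K -> 1)
    leaves the combination undefined and raises.
    """
    combined: dict[frozenset, float] = {}
    conflict = 0.0
    for (b, mb), (c, mc) in product(m1.masses.items(), m2.masses.items()):
        inter = b & c
        w = mb * mc
        if w == 0.0:
            continue
        if inter:
            combined[inter] = combined.get(inter, 0.0) + w
        else:
            conflict += w
    if conflict >= 1.0 - _CONFLICT_TOL:
        raise ValueError("total conflict (K = 1): Dempster combination undefined")
    norm = 1.0 - conflict
    return MassFunction({focal: m / norm for focal, m in combined.items()})


def fuse_decision(m: MassFunction) -> tuple[int, float, bool]:
    """Pick the singleton of maximum mass.

    Returns ``(state, confidence, tied)``; exact ties break to the first
    state in canonical order (-1, 0, 1) and are flagged.  If every
    singleton carries zero mass the decision is undecidable.
    """
    singles = m.singleton_masses()
    best = max(singles.values())
    if best <= 0.0:
        raise ValueError("undecidable: all singleton masses are zero")
    winners = [s for s in STATES if singles[s] == best]
    return winners[0], best, len(winners) > 1


def estimate_credibility(cv_acc_semg: float, cv_acc_ecg: float) -> CredibilityWeights:
    """Normalise two cross-validated accuracies into credibility weights."""
    for name, acc in (("sEMG", cv_acc_semg), ("ECG", cv_acc_ecg)):
        if not 0.0 <= acc <= 1.0:
            raise ValueError(f"{name} accuracy must lie in [0, 1], got {acc}")
    total = cv_acc_semg + cv_acc_ecg
    if total == 0.0:
        raise ValueError("both accuracies are zero; credibility undefined")
    return CredibilityWeights(c_semg=cv_acc_semg / total, c_ecg=cv_acc_ecg / total)


def fuse_probabilities(
    p_semg: StateProbabilities,
    p_ecg: StateProbabilities,
    weights: CredibilityWeights = DEFAULT_CREDIBILITY,
) -> tuple[int, float, MassFunction]:
    """Convenience pipeline: discount both modalities, combine, decide."""
    m = dempster_combine(
        make_bpa(p_semg, weights.c_semg), make_bpa(p_ecg, weights.c_ecg)
    )
    state, conf, _tied = fuse_decision(m)
    return state, conf, m
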