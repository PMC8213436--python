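"""Annotation of observed MS features against a compound library.

Matching is by exact mass only: a feature is assigned every (compound,
adduct) pair whose theoretical m/z lies within the tolerance window,
|error| <= 5 mDa OR |relative error| <= 10 ppm, both bounds inclusive.
Retention time is carried through but never used for matching.  All
candidate matches are retained — identifications at this stage are
tentative and no winner is picked automatically.

Fragment ions are explained by neutral-loss arithmetic: a small multiset
of losses (rhamnose/glucose residues, water, CO2, ...) whose summed mass
accounts for the precursor-minus-fragment difference within the same
tolerance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .formula import AdductRule, adducts_for_polarity, formula_mass

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "MSFeature",
    "AnnotationMatch",
    "NeutralLoss",
    "FragmentAssignment",
    "Tolerance",
    "DEFAULT_TOLERANCE",
    "NEUTRAL_LOSSES",
    "ppm_error",
    "mda_error",
    "match_features",
    "annotate_fragments",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound: name, Hill formula, herb of origin and the
    MS response used downstream as a content proxy."""

    name: str
    formula: str
    herb: str = ""
    response: float = 0.0


@dataclass(frozen=True)
class MSFeature:
    """One observed ion: retention time (min), m/z, intensity, polarity."""

    rt: float
    mz: float
    response: float
    polarity: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.response < 0:
            raise ValueError(f"response must be non-negative, got {self.response}")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")


@dataclass(frozen=True)
class AnnotationMatch:
    """A tolerance-scored assignment of a feature to a library compound."""

    feature: MSFeature
    compound: str
    adduct: str
    theoretical_mz: float
    error_mda: float
    error_ppm: float


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral loss (e.g. rhamnose residue rha = C6H10O4)."""

    label: str
    formula: str
    mass: float

    @classmethod
    def from_formula(cls, label: str, formula: str) -> "NeutralLoss":
        return cls(label, formula, formula_mass(formula))


@dataclass(frozen=True)
class FragmentAssignment:
    """A fragment m/z and the loss multiset that explains it (or none)."""

    fragment_mz: float
    losses: Optional[tuple[str, ...]]  # sorted loss labels, with repeats
    error_mda: Optional[float]

    @property
    def label(self) -> str:
        """Compact label like '-2rha-Glc'; empty when unassigned."""
        if not self.losses:
            return ""
        out = []
        for name, grp in itertools.groupby(self.losses):
            n = len(list(grp))
            out.append(f"-{n if n > 1 else ''}{name}")
        return "".join(out)


@dataclass(frozen=True)
class Tolerance:
    """Inclusive disjunctive mass-error window: |Δ| <= mda OR |Δppm| <= ppm."""

    mda: float = 5.0
    ppm: float = 10.0

    def __post_init__(self) -> None:
        if self.mda <= 0 or self.ppm <= 0:
            raise ValueError("tolerance bounds must be positive")

    def accepts(self, observed: float, theoretical: float) -> bool:
        return (
            abs(mda_error(observed, theoretical)) <= self.mda
            or abs(ppm_error(observed, theoretical)) <= self.ppm
        )


DEFAULT_TOLERANCE = Tolerance()


def _load_losses() -> list[NeutralLoss]:
    text = resources.files("herbnet.data").joinpath("neutral_losses.tsv").read_text()
    losses = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, formula = line.split("\t")
        losses.append(NeutralLoss.from_formula(label, formula))
    return losses


#: Bundled default neutral losses (rha, Glc, H2O, CO2, C4H7, C4H8O4, C3H6O3).
NEUTRAL_LOSSES: list[NeutralLoss] = _load_losses()


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def mda_error(observed: float, theoretical: float) -> float:
    """Signed absolute mass error in millidaltons."""
    return 1e3 * (observed - theoretical)


def match_features(
    features: Iterable[MSFeature],
    library: Sequence[CompoundRecord],
    adducts: Optional[Sequence[AdductRule]] = None,
    tolerance: Tolerance = DEFAULT_TOLERANCE,
) -> list[AnnotationMatch]:
    """Match observed features to library compounds under the mass tolerance.

    Every (feature, compound, adduct) triple within tolerance is emitted;
    a feature may carry several candidate matches.  The result is sorted by
    absolute error (mDa), with compound name then adduct label as stable
    tie-breakers.

    ``adducts`` restricts the registry; by default every registered adduct
    of the feature's polarity is tried.
    """
    library = list(library)
    if not library:
        logger.warning("empty compound library: no annotations possible")
        return []
    # precompute neutral masses once; parse errors surface with the compound name
    masses = []
    for rec in library:
        try:
            masses.append(formula_mass(rec.formula))
        except Exception as exc:
            raise type(exc)(f"compound {rec.name!r}: {exc}") from None

    by_polarity = {
        "+": [r for r in (adducts or adducts_for_polarity("+")) if r.polarity == "+"],
        "-": [r for r in (adducts or adducts_for_polarity("-")) if r.polarity == "-"],
    }

    matches: list[AnnotationMatch] = []
    for feat in features:
        for rec, mass in zip(library, masses):
            for rule in by_polarity[feat.polarity]:
                theo = rule.mz(mass)
                if tolerance.accepts(feat.mz, theo):
                    matches.append(
                        AnnotationMatch(
                            feature=feat,
                            compound=rec.name,
                            adduct=rule.label,
                            theoretical_mz=theo,
                            error_mda=mda_error(feat.mz, theo),
                            error_ppm=ppm_error(feat.mz, theo),
                        )
                    )
    matches.sort(key=lambda m: (abs(m.error_mda), m.compound, m.adduct))
    return matches


def annotate_fragments(
    precursor_mz: float,
    fragment_mzs: Sequence[float],
    losses: Optional[Sequence[NeutralLoss]] = None,
    tolerance: Tolerance = DEFAULT_TOLERANCE,
    max_losses: int = 4,
    max_each: int = 3,
) -> list[FragmentAssignment]:
    """Explain fragment ions as the precursor minus a multiset of neutral losses.

    For each fragment, multisets of up to ``max_losses`` losses (each label
    used at most ``max_each`` times) are searched; the multiset whose summed
    mass best explains ``precursor_mz - fragment_mz`` within tolerance is
    assigned.  Unexplained fragments come back with ``losses=None``.
    """
    if losses is None:
        losses = NEUTRAL_LOSSES
    if not losses:
        raise ValueError("at least one neutral loss is required")
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")

    # enumerate loss multisets once; modest sizes by construction
    combos: list[tuple[tuple[str, ...], float]] = []
    n_capped = 0
    for k in range(1, max_losses + 1):
        for combo in itertools.combinations_with_replacement(losses, k):
            if any(sum(1 for c in combo if c.label == l.label) > max_each for l in combo):
                n_capped += 1
                continue
            labels = tuple(sorted(c.label for c in combo))
            combos.append((labels, sum(c.mass for c in combo)))
    if n_capped:
        logger.debug("capped %d loss multisets exceeding %d per label", n_capped, max_each)

    out: list[FragmentAssignment] = []
    for frag in fragment_mzs:
        best: Optional[tuple[float, tuple[str, ...]]] = None
        for labels, mass in combos:
            # tolerance applies to the implied fragment m/z, not the loss sum
            implied = precursor_mz - mass
            if tolerance.accepts(frag, implied):
                err = abs(mda_error(frag, implied))
                if best is None or err < best[0]:
                    best = (err, labels)
        if best is None:
            out.append(FragmentAssignment(frag, None, None))
        else:
            err, labels = best
            out.append(FragmentAssignment(frag, labels, err))
    return out
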