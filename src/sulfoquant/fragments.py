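"""Negative-mode MS/MS fragment prediction for sulfolipids.

Collision-induced dissociation of deprotonated sulfoquinovosyl glycerolipids
produces two families of product ions:

* headgroup diagnostics — low-mass ions from the sulfoquinovose moiety
  (nominal m/z 81, 125, 153, 165, 225, 255) that are common to all
  sulfolipids and make a precursor attributable to the class at all;
* fatty-acid neutral losses — per acyl chain, loss of the free acid
  (CnH(2n−2d)O2) or of the corresponding ketene (CnH(2n−2d−2)O), which
  encode the acyl composition of the individual species.

The sn1 acyl loss is empirically the more intense one, which is what
:func:`rank_sn_assignment` exploits to order an acyl pair on the glycerol
backbone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

from .elements import ElementCount
from .species import (
    DEFAULT_POOL,
    AcylChain,
    FattyAcidPool,
    LipidClass,
    SulfolipidSpecies,
    elemental_formula,
    enumerate_species,
    mz_deprotonated,
)


class FragmentKind(str, enum.Enum):
    DIAGNOSTIC = "diagnostic"
    ACID_LOSS = "acid_loss"
    KETENE_LOSS = "ketene_loss"
    CARBOXYLATE = "carboxylate"


@dataclass(frozen=True)
class FragmentPrediction:
    mz_nominal: int
    kind: FragmentKind
    mz_monoisotopic: float | None = None
    lost_chain: AcylChain | None = None
    formula: ElementCount | None = None
    label: str = ""
    assignment_uncertain: bool = False


def _anion(formula: str, nominal: int, label: str, kind: FragmentKind = FragmentKind.DIAGNOSTIC,
           uncertain: bool = False) -> FragmentPrediction:
    comp = ElementCount.from_formula(formula)
    assert comp.nominal_mass == nominal
    return FragmentPrediction(
        mz_nominal=nominal,
        kind=kind,
        mz_monoisotopic=comp.monoisotopic_mass,
        formula=comp,
        label=label,
        assignment_uncertain=uncertain,
    )


def diagnostic_fragments() -> list[FragmentPrediction]:
    """The six sulfoquinovose-derived ions common to all sulfolipids.

    Elemental assignments for m/z 81, 153, 165 and 225 are established;
    m/z 125 and the palmitate carboxylate reading of m/z 255 are plausible
    but flagged ``assignment_uncertain`` — matching uses nominal values only.
    """
    return [
        _anion("HSO3", 81, "bisulfite HSO3-"),
        _anion("C2H5O4S", 125, "C2H5O4S- (tentative)", uncertain=True),
        _anion("C3H5O5S", 153, "C3H5O5S-"),
        _anion("C4H5O5S", 165, "C4H5O5S-"),
        _anion("C6H9O7S", 225, "dehydrated deprotonated sulfoquinovose C6H9O7S-"),
        _anion("C16H31O2", 255, "palmitate carboxylate (tentative)",
               kind=FragmentKind.CARBOXYLATE, uncertain=True),
    ]


DIAGNOSTIC_NOMINAL_MZ = frozenset(f.mz_nominal for f in diagnostic_fragments())


def neutral_loss_fragments(species: SulfolipidSpecies) -> list[FragmentPrediction]:
    """Acid- and ketene-loss fragments of [M-H]⁻, one pair per distinct chain.

    Mass balance holds exactly: precursor = fragment + neutral loss on both
    the monoisotopic and the nominal scale.
    """
    precursor_formula = elemental_formula(species) - ElementCount(H=1)
    mono = mz_deprotonated(species, "monoisotopic")
    nominal = mz_deprotonated(species, "nominal")
    out = []
    for chain in dict.fromkeys(species.chains):  # dedupe identical chains
        for kind, loss in (
            (FragmentKind.ACID_LOSS, chain.free_acid_formula),
            (FragmentKind.KETENE_LOSS, chain.ketene_formula),
        ):
            out.append(FragmentPrediction(
                mz_nominal=nominal - loss.nominal_mass,
                kind=kind,
                mz_monoisotopic=mono - loss.monoisotopic_mass,
                lost_chain=chain,
                formula=precursor_formula - loss,
                label=f"[M-H-{chain}{'' if kind is FragmentKind.ACID_LOSS else ' ketene'}]-",
            ))
    return out


@dataclass(frozen=True)
class SnAssignment:
    sn1_chain: AcylChain
    sn2_chain: AcylChain
    confidence: str  # "assigned" | "ambiguous"


def rank_sn_assignment(
    species: SulfolipidSpecies,
    loss_intensities: dict[AcylChain, float],
) -> SnAssignment:
    """Order an SQDG acyl pair by the intensities of their acid-loss fragments.

    The chain whose loss fragment is the more intense is placed sn1; equal or
    missing intensities yield an ambiguous assignment, as do SQDGs with two
    identical chains (their loss fragments coincide).
    """
    if species.lipid_class is not LipidClass.SQDG:
        raise ValueError("sn ranking requires an SQDG (two chains)")
    a, b = species.chains
    if a == b:
        return SnAssignment(a, b, "ambiguous")
    ia, ib = loss_intensities.get(a), loss_intensities.get(b)
    if ia is None or ib is None or ia == ib:
        return SnAssignment(a, b, "ambiguous")
    if ia > ib:
        return SnAssignment(a, b, "assigned")
    return SnAssignment(b, a, "assigned")


@dataclass(frozen=True)
class AnnotationCandidate:
    species: SulfolipidSpecies
    n_matched: int
    matched: tuple[tuple[float, FragmentPrediction], ...] = field(repr=False)
    total_mass_error: float

    @property
    def name(self) -> str:
        from .species import nominal_name

        return nominal_name(self.species)


def _match_error(observed: float, frag: FragmentPrediction, tolerance: float) -> float | None:
    """Smallest |observed − predicted| within tolerance, or None.

    Uncertain assignments are matched on the nominal value only.
    """
    candidates = [float(frag.mz_nominal)]
    if frag.mz_monoisotopic is not None and not frag.assignment_uncertain:
        candidates.append(frag.mz_monoisotopic)
    err = min(abs(observed - c) for c in candidates)
    return err if err <= tolerance else None


def annotate_precursor(
    precursor_mz: float,
    product_mzs: Iterable[float],
    tolerance: float = 0.5,
    pool: FattyAcidPool = DEFAULT_POOL,
) -> list[AnnotationCandidate]:
    """Rank candidate sulfolipids for an observed precursor/product pattern.

    Candidates are every SQMG/SQDG from ``pool`` whose monoisotopic [M-H]⁻
    lies within ``tolerance`` of the observed precursor; they are ranked by
    the number of observed products explained by their predicted diagnostic
    and neutral-loss fragments, ties broken by the summed absolute mass
    error.  Fragment intensity carries no weight (no intensity model).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    products = list(product_mzs)
    diagnostics = diagnostic_fragments()

    candidates = []
    seen: set[SulfolipidSpecies] = set()
    for nominal in {int(precursor_mz // 1), int(-(-precursor_mz // 1))}:
        for cls in (LipidClass.SQDG, LipidClass.SQMG):
            if nominal <= 0:
                continue
            for sp in enumerate_species(nominal, cls, pool):
                if sp in seen:
                    continue
                seen.add(sp)
                if abs(mz_deprotonated(sp, "monoisotopic") - precursor_mz) > tolerance:
                    continue
                predicted = diagnostics + neutral_loss_fragments(sp)
                matched = []
                total_err = 0.0
                for obs in products:
                    best: tuple[float, FragmentPrediction] | None = None
                    for frag in predicted:
                        err = _match_error(obs, frag, tolerance)
                        if err is not None and (best is None or err < best[0]):
                            best = (err, frag)
                    if best is not None:
                        matched.append((obs, best[1]))
                        total_err += best[0]
                candidates.append(AnnotationCandidate(
                    species=sp,
                    n_matched=len(matched),
                    matched=tuple(matched),
                    total_mass_error=total_err,
                ))
    candidates.sort(key=lambda c: (-c.n_matched, c.total_mass_error, str(c.species)))
    return candidates


def annotations_to_records(
    precursor_mz: float, candidates: list[AnnotationCandidate]
) -> list[dict]:
    """Flatten annotation results for CSV/JSON export."""
    return [
        {
            "precursor_mz": precursor_mz,
            "candidate": c.name,
            "chains": c.species.chain_label(),
            "n_matched": c.n_matched,
            "matched_products": ";".join(f"{obs:g}={frag.label or frag.mz_nominal}"
                                          for obs, frag in c.matched),
            "total_mass_error": round(c.total_mass_error, 4),
        }
        for c in candidates
    ]
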