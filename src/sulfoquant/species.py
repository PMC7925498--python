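"""Sulfolipid species model.

Sulfoquinovosyl glycerolipids consist of a sulfoquinovose headgroup
(6-deoxy-6-sulfo-glucose) glycosidically bound to glycerol, with one (SQMG)
or two (SQDG) fatty acids esterified to the glycerol backbone.  The
sulfoquinovosyl-glycerol core is C9H18O10S; each esterification removes one
water.  In negative electrospray the strongly acidic sulfonate group makes
these lipids appear almost exclusively as the deprotonated ion [M-H]⁻.

Species are conventionally labelled by the nominal m/z of [M-H]⁻
("SQDG 815"), which is how triple-quadrupole MRM panels address them; the
commercial standard is sold under its neutral nominal mass ("SQDG 816"),
kept here as an alias.
"""

from __future__ import annotations

import csv
import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from .elements import HYDROGEN_MASS, WATER, ElementCount

#: sulfoquinovosyl-glycerol core: sulfoquinovose (C6H12O8S) + glycerol
#: (C3H8O3) − H2O from the glycosidic bond.
CORE_FORMULA = ElementCount.from_formula("C9H18O10S")


class LipidClass(str, enum.Enum):
    SQMG = "SQMG"
    SQDG = "SQDG"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty-acyl chain in C:D shorthand (total carbons : double bonds)."""

    carbons: int
    double_bonds: int
    sn_position: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        max_db = (self.carbons - 2) // 2
        if not 0 <= self.double_bonds <= max_db:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} impossible "
                f"(0 <= double bonds <= {max_db})"
            )
        if self.sn_position not in (None, "sn1", "sn2", "unknown"):
            raise ValueError(f"bad sn position {self.sn_position!r}")

    @classmethod
    def from_string(cls, text: str, sn_position: str | None = None) -> "AcylChain":
        c, _, d = text.strip().partition(":")
        if not d:
            raise ValueError(f"chain must be 'C:D', got {text!r}")
        return cls(int(c), int(d), sn_position)

    @property
    def free_acid_formula(self) -> ElementCount:
        """The free fatty acid CnH(2n−2d)O2."""
        n, d = self.carbons, self.double_bonds
        return ElementCount(C=n, H=2 * n - 2 * d, O=2)

    @property
    def ketene_formula(self) -> ElementCount:
        """The fatty-acyl ketene CnH(2n−2d−2)O (acid − H2O)."""
        n, d = self.carbons, self.double_bonds
        return ElementCount(C=n, H=2 * n - 2 * d - 2, O=1)

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


#: acyl chains commonly esterified in cyanobacterial / plant glycolipids
DEFAULT_CHAINS = (
    "14:0", "15:0", "16:0", "16:1", "17:0", "18:0", "18:1", "18:2",
    "18:3", "18:4", "20:4", "20:5", "22:6",
)


@dataclass(frozen=True)
class FattyAcidPool:
    """The chain templates allowed when enumerating isobaric species."""

    chains: tuple[AcylChain, ...]

    def __post_init__(self) -> None:
        seen = set()
        for ch in self.chains:
            key = (ch.carbons, ch.double_bonds)
            if key in seen:
                raise ValueError(f"duplicate chain {ch} in pool")
            seen.add(key)

    @classmethod
    def from_strings(cls, chains: Iterable[str]) -> "FattyAcidPool":
        return cls(tuple(AcylChain.from_string(c) for c in chains))

    def __iter__(self):
        return iter(self.chains)

    def __len__(self) -> int:
        return len(self.chains)


DEFAULT_POOL = FattyAcidPool.from_strings(DEFAULT_CHAINS)


@dataclass(frozen=True)
class SulfolipidSpecies:
    """An SQMG (one chain) or SQDG (two chains).

    Chains are stored as an unordered pair unless sn positions are known:
    the MRM precursor mass cannot distinguish regiochemistry.
    """

    lipid_class: LipidClass
    chains: tuple[AcylChain, ...]

    def __post_init__(self) -> None:
        expected = 1 if self.lipid_class is LipidClass.SQMG else 2
        if len(self.chains) != expected:
            raise ValueError(
                f"{self.lipid_class.value} requires {expected} chain(s), "
                f"got {len(self.chains)}"
            )
        # canonical unordered storage
        object.__setattr__(self, "chains", tuple(sorted(self.chains)))

    @classmethod
    def sqmg(cls, chain: str | AcylChain) -> "SulfolipidSpecies":
        if isinstance(chain, str):
            chain = AcylChain.from_string(chain)
        return cls(LipidClass.SQMG, (chain,))

    @classmethod
    def sqdg(cls, chain1: str | AcylChain, chain2: str | AcylChain) -> "SulfolipidSpecies":
        chains = tuple(
            AcylChain.from_string(c) if isinstance(c, str) else c
            for c in (chain1, chain2)
        )
        return cls(LipidClass.SQDG, chains)

    def chain_label(self) -> str:
        return "/".join(str(c) for c in self.chains)

    def __str__(self) -> str:
        return f"{self.lipid_class.value}({self.chain_label()})"


def formula_from_chains(chains: Sequence[AcylChain]) -> ElementCount:
    """Core + Σ free acids − one esterification water per chain.

    Accepts zero chains (bare sulfoquinovosyl glycerol) so that the additive
    structure can be probed directly.
    """
    total = CORE_FORMULA
    for chain in chains:
        total = total + chain.free_acid_formula - WATER
    return total


def elemental_formula(species: SulfolipidSpecies) -> ElementCount:
    """Elemental composition of the neutral species."""
    return formula_from_chains(species.chains)


def mz_deprotonated(species: SulfolipidSpecies, mode: str = "monoisotopic") -> float | int:
    """m/z of [M-H]⁻ on the requested mass scale.

    ``monoisotopic``: Σ monoisotopic atomic masses − mass of H (electron
    mass neglected).  ``nominal``: Σ integer mass numbers − 1.
    """
    formula = elemental_formula(species)
    if mode == "monoisotopic":
        return formula.monoisotopic_mass - HYDROGEN_MASS
    if mode == "nominal":
        return formula.nominal_mass - 1
    raise ValueError(f"mode must be 'monoisotopic' or 'nominal', got {mode!r}")


def nominal_name(species: SulfolipidSpecies) -> str:
    """Panel-style display name: class + nominal [M-H]⁻, e.g. ``"SQDG 815"``."""
    return f"{species.lipid_class.value} {mz_deprotonated(species, 'nominal')}"


def neutral_nominal_alias(species: SulfolipidSpecies) -> str:
    """Vendor-style alias using the neutral nominal mass, e.g. ``"SQDG 816"``."""
    return f"{species.lipid_class.value} {elemental_formula(species).nominal_mass}"


def enumerate_species(
    precursor_nominal: int,
    lipid_class: LipidClass | str = LipidClass.SQDG,
    pool: FattyAcidPool = DEFAULT_POOL,
) -> list[SulfolipidSpecies]:
    """All unordered chain combinations from ``pool`` whose nominal [M-H]⁻
    equals ``precursor_nominal``.

    MRM precursors at unit resolution cannot separate isobaric acyl
    combinations, so one precursor typically maps to several candidates
    (e.g. 815 → 16:0/18:3 and 16:1/18:2).
    """
    if precursor_nominal <= 0:
        raise ValueError("precursor_nominal must be positive")
    lipid_class = LipidClass(lipid_class)
    n_chains = 1 if lipid_class is LipidClass.SQMG else 2
    out = []
    for combo in itertools.combinations_with_replacement(sorted(pool), n_chains):
        sp = SulfolipidSpecies(lipid_class, combo)
        if mz_deprotonated(sp, "nominal") == precursor_nominal:
            out.append(sp)
    return out


# ---------------------------------------------------------------------------
# species list CSV I/O

SPECIES_CSV_COLUMNS = (
    "name", "lipid_class", "chain1", "chain2",
    "formula", "mz_monoisotopic", "mz_nominal",
)


def write_species_csv(species: Iterable[SulfolipidSpecies], sink: str | Path | IO[str]) -> None:
    close = False
    if isinstance(sink, (str, Path)):
        sink = open(sink, "w", newline="")
        close = True
    try:
        writer = csv.writer(sink)
        writer.writerow(SPECIES_CSV_COLUMNS)
        for sp in species:
            chains = [str(c) for c in sp.chains] + [""]
            writer.writerow([
                nominal_name(sp),
                sp.lipid_class.value,
                chains[0],
                chains[1],
                elemental_formula(sp).formula(),
                f"{mz_deprotonated(sp, 'monoisotopic'):.4f}",
                mz_deprotonated(sp, "nominal"),
            ])
    finally:
        if close:
            sink.close()


def read_species_csv(source: str | Path | IO[str]) -> list[SulfolipidSpecies]:
    close = False
    if isinstance(source, (str, Path)):
        source = open(source, newline="")
        close = True
    try:
        reader = csv.DictReader(source)
        out = []
        for row in reader:
            cls = LipidClass(row["lipid_class"])
            chains = [AcylChain.from_string(row["chain1"])]
            if row.get("chain2"):
                chains.append(AcylChain.from_string(row["chain2"]))
            out.append(SulfolipidSpecies(cls, tuple(chains)))
        return out
    finally:
        if close:
            source.close()
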