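"""MRM transition panels: model, CSV round-trip, generation, and queries.

A panel lists, per analyte, three precursor→product transitions acquired on
a triple quadrupole: one quantifier (integrated for quantification) and two
qualifiers (identity confirmation).  The bundled reference panel covers the
cerebroside internal standard, one SQMG and 25 SQDGs as screened from an
*Arthrospira* sp. extract; product ions carry instrument-tuned decimals
(e.g. the sulfonate ion appears anywhere between 79.9 and 81.1), so all
matching is tolerance-based rather than exact.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO

from .species import SulfolipidSpecies, mz_deprotonated

PANEL_CSV_COLUMNS = (
    "analyte", "class", "rt_min", "precursor_mz", "product_mz", "role",
    "dwell_ms", "dp_v", "ep_v", "ce", "cxp_v",
)
_OPTIONAL_COLUMNS = ("molar_mass_g_mol",)

#: nominal sulfoquinovose product ions observed across the panel (the
#: instrument-tuned 224/80/94/164 variants are the same ions offset by <=1).
SULFOLIPID_PRODUCT_NOMINALS = frozenset({80, 81, 95, 153, 165, 225})


class Role(str, enum.Enum):
    QUANTIFIER = "quantifier"
    QUALIFIER1 = "qualifier1"
    QUALIFIER2 = "qualifier2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PanelError(ValueError):
    """Malformed panel file or panel invariant violation."""


@dataclass(frozen=True)
class MRMTransition:
    analyte: str
    role: Role
    precursor_mz: float
    product_mz: float
    dwell_ms: float = 150.0
    dp_v: float = -150.0
    ep_v: float = -10.0
    ce: float = -100.0
    cxp_v: float = -5.0

    def __post_init__(self) -> None:
        if not self.precursor_mz > self.product_mz > 0:
            raise ValueError(
                f"{self.analyte}: require precursor > product > 0, got "
                f"{self.precursor_mz} -> {self.product_mz}"
            )
        if self.dwell_ms <= 0:
            raise ValueError(f"{self.analyte}: dwell time must be positive")


@dataclass(frozen=True)
class PanelAnalyte:
    name: str
    lipid_class: str  # "SQMG" | "SQDG" | "ISD"
    transitions: tuple[MRMTransition, ...]
    rt_min: float | None = None
    molar_mass_g_mol: float | None = None

    def __post_init__(self) -> None:
        if self.lipid_class not in ("SQMG", "SQDG", "ISD"):
            raise PanelError(f"{self.name}: unknown class {self.lipid_class!r}")
        if len(self.transitions) != 3:
            raise PanelError(
                f"analyte {self.name}: expected 3 transitions, got {len(self.transitions)}"
            )
        roles = [t.role for t in self.transitions]
        if roles.count(Role.QUANTIFIER) != 1:
            raise PanelError(f"analyte {self.name}: exactly one quantifier required")
        if len(set(roles)) != 3:
            raise PanelError(f"analyte {self.name}: duplicate transition roles")

    @property
    def quantifier(self) -> MRMTransition:
        return next(t for t in self.transitions if t.role is Role.QUANTIFIER)


@dataclass(frozen=True)
class TransitionPanel:
    analytes: tuple[PanelAnalyte, ...]
    _by_name: dict[str, PanelAnalyte] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_name: dict[str, PanelAnalyte] = {}
        for an in self.analytes:
            if an.name in by_name:
                raise PanelError(f"duplicate analyte {an.name!r}")
            by_name[an.name] = an
        object.__setattr__(self, "_by_name", by_name)

    def __len__(self) -> int:
        return len(self.analytes)

    def __iter__(self):
        return iter(self.analytes)

    def __getitem__(self, name: str) -> PanelAnalyte:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"analyte {name!r} not in panel") from None

    @property
    def transitions(self) -> list[MRMTransition]:
        return [t for an in self.analytes for t in an.transitions]

    def classify_analyte(self, key: str | float) -> str:
        """Class tag for an analyte addressed by name or precursor m/z."""
        if isinstance(key, str):
            return self[key].lipid_class
        best = min(
            self.analytes,
            key=lambda an: abs(an.quantifier.precursor_mz - float(key)),
            default=None,
        )
        if best is None or abs(best.quantifier.precursor_mz - float(key)) > 0.5:
            raise KeyError(f"no analyte near precursor {key}")
        return best.lipid_class

    def count_by_class(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for an in sorted(self.analytes, key=lambda a: a.name):
            counts[an.lipid_class] = counts.get(an.lipid_class, 0) + 1
        return counts


def load_panel(source: str | Path | IO[str]) -> TransitionPanel:
    """Read a panel CSV (see :data:`PANEL_CSV_COLUMNS`); parse errors carry
    the offending line number."""
    close = False
    if isinstance(source, (str, Path)):
        source = open(source, newline="")
        close = True
    try:
        reader = csv.DictReader(source)
        if reader.fieldnames is None:
            raise PanelError("empty panel file")
        missing = set(PANEL_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise PanelError(f"panel header missing columns: {sorted(missing)}")

        groups: dict[str, dict] = {}
        order: list[str] = []
        for row in reader:
            line = reader.line_num
            name = (row.get("analyte") or "").strip()
            if not name:
                raise PanelError(f"line {line}: missing analyte name")
            try:
                transition = MRMTransition(
                    analyte=name,
                    role=Role(row["role"].strip()),
                    precursor_mz=float(row["precursor_mz"]),
                    product_mz=float(row["product_mz"]),
                    dwell_ms=float(row["dwell_ms"]),
                    dp_v=float(row["dp_v"]),
                    ep_v=float(row["ep_v"]),
                    ce=float(row["ce"]),
                    cxp_v=float(row["cxp_v"]),
                )
                rt = float(row["rt_min"]) if (row.get("rt_min") or "").strip() else None
                mm_raw = (row.get("molar_mass_g_mol") or "").strip()
                molar_mass = float(mm_raw) if mm_raw else None
                cls = row["class"].strip()
            except (KeyError, ValueError) as exc:
                if isinstance(exc, PanelError):
                    raise
                raise PanelError(f"line {line}: malformed row ({exc})") from exc
            if name not in groups:
                groups[name] = {"class": cls, "rt": rt, "mm": molar_mass,
                                "transitions": [], "line": line}
                order.append(name)
            elif order[-1] != name:
                raise PanelError(
                    f"line {line}: duplicate analyte {name!r} (rows not contiguous)"
                )
            groups[name]["transitions"].append(transition)

        analytes = []
        for name in order:
            g = groups[name]
            try:
                analytes.append(PanelAnalyte(
                    name=name,
                    lipid_class=g["class"],
                    transitions=tuple(g["transitions"]),
                    rt_min=g["rt"],
                    molar_mass_g_mol=g["mm"],
                ))
            except PanelError as exc:
                raise PanelError(f"near line {g['line']}: {exc}") from None
        if not analytes:
            raise PanelError("panel contains no analytes")
        return TransitionPanel(tuple(analytes))
    finally:
        if close:
            source.close()


def write_panel(panel: TransitionPanel, sink: str | Path | IO[str]) -> None:
    close = False
    if isinstance(sink, (str, Path)):
        sink = open(sink, "w", newline="")
        close = True
    try:
        writer = csv.writer(sink)
        writer.writerow(PANEL_CSV_COLUMNS + _OPTIONAL_COLUMNS)
        for an in panel:
            for t in an.transitions:
                writer.writerow([
                    an.name, an.lipid_class,
                    "" if an.rt_min is None else an.rt_min,
                    t.precursor_mz, t.product_mz, t.role.value,
                    t.dwell_ms, t.dp_v, t.ep_v, t.ce, t.cxp_v,
                    "" if an.molar_mass_g_mol is None else an.molar_mass_g_mol,
                ])
    finally:
        if close:
            sink.close()


def load_reference_panel() -> TransitionPanel:
    """The bundled reference panel (ISD + 26 sulfolipids, 81 transitions)."""
    ref = resources.files("sulfoquant.data") / "sulfolipid_mrm_panel.csv"
    with ref.open(newline="") as fh:
        return load_panel(fh)


def load_reference_shares() -> dict[str, dict[str, float]]:
    """Published *Arthrospira* composition shares (%) for the SQDG/SQMG
    species reported by both the present MRM method and an independent
    UHPLC-HRMS study; a cross-method fixture, not computed data."""
    ref = resources.files("sulfoquant.data") / "spirulina_reference_shares.csv"
    out: dict[str, dict[str, float]] = {}
    with ref.open(newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["analyte"]] = {
                "uhplc_hrms": float(row["share_pct_uhplc_hrms"]),
                "mrm": float(row["share_pct_mrm"]),
            }
    return out


@dataclass(frozen=True)
class InstrumentDefaults:
    """QqQ potentials applied to generated transitions (tune-file surrogates)."""

    dwell_ms: float = 150.0
    dp_v: float = -150.0
    ep_v: float = -10.0
    ce: float = -100.0
    cxp_v: float = -5.0


def generate_transitions(
    species: SulfolipidSpecies,
    defaults: InstrumentDefaults = InstrumentDefaults(),
    qualifier_products: tuple[float, float] = (225.0, 165.0),
) -> tuple[MRMTransition, MRMTransition, MRMTransition]:
    """Propose the three standard transitions for a sulfolipid species.

    The quantifier monitors the sulfonate diagnostic (m/z 81), the qualifiers
    two further sulfoquinovose ions from the {225, 165, 153, 95} family —
    the dominant pattern across the reference panel.  The precursor is the
    monoisotopic [M-H]⁻ rounded to one decimal, as a unit-resolution Q1 is
    set in practice.
    """
    allowed = {225.0, 165.0, 153.0, 95.0}
    if set(qualifier_products) - allowed:
        raise ValueError(f"qualifier products must come from {sorted(allowed)}")
    precursor = round(mz_deprotonated(species, "monoisotopic"), 1)
    name = f"{mz_deprotonated(species, 'nominal')}"
    kw = dict(analyte=name, precursor_mz=precursor, dwell_ms=defaults.dwell_ms,
              dp_v=defaults.dp_v, ep_v=defaults.ep_v, ce=defaults.ce,
              cxp_v=defaults.cxp_v)
    return (
        MRMTransition(role=Role.QUANTIFIER, product_mz=81.0, **kw),
        MRMTransition(role=Role.QUALIFIER1, product_mz=qualifier_products[0], **kw),
        MRMTransition(role=Role.QUALIFIER2, product_mz=qualifier_products[1], **kw),
    )


def match_transition(
    precursor_mz: float,
    product_mz: float,
    panel: TransitionPanel,
    tolerance: float = 0.5,
) -> tuple[str, Role] | None:
    """Nearest panel transition within ``tolerance`` on both ions.

    Ambiguity (two transitions inside the tolerance box) is resolved to the
    nearest by summed distance, with a warning.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    hits = []
    for t in panel.transitions:
        dq1 = abs(t.precursor_mz - precursor_mz)
        dq3 = abs(t.product_mz - product_mz)
        if dq1 <= tolerance and dq3 <= tolerance:
            hits.append((dq1 + dq3, t))
    if not hits:
        return None
    hits.sort(key=lambda h: h[0])
    if len(hits) > 1 and not all(h[1].analyte == hits[0][1].analyte and
                                 h[1].role == hits[0][1].role for h in hits[1:]):
        warnings.warn(
            f"ambiguous transition match for {precursor_mz}->{product_mz}: "
            f"{len(hits)} candidates, keeping nearest", stacklevel=2,
        )
    best = hits[0][1]
    return best.analyte, best.role
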