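"""ΔG→Kd conversion and domain-based T-type vs L-type selectivity triage.

A docking table assigns each compound × receptor pair a predicted binding
free energy ΔG (kcal/mol, more negative = stronger) and the pore domain
the best pose engages.  The screening rule encoded here reflects how
phenylalkylamines plug the two channel families: a compound *binds TCC*
when any T-type receptor (α1G, α1H, α1I) reports a pose in domain I or
IV, and *binds LCC* when the L-type receptor α1C reports a pose in
domain III or IV.  Crossing the two booleans partitions compounds into
TCC_selective / LCC_selective / dual_blocker / non_binder; the
TCC-selective ones are the blocker candidates worth pursuing.

Missing ΔG ("N/A") always means "no predicted binding", never zero, and
dominates any printed domain annotation.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequences import ResidueLabel, SequenceError, normalize_channel

__all__ = [
    "TCC_RECEPTORS",
    "LCC_RECEPTOR",
    "CATEGORIES",
    "SelectivityError",
    "DockingRecord",
    "BindingAffinity",
    "SelectivityReport",
    "delta_g_to_kd",
    "load_docking_table",
    "classify_selectivity",
    "classify_table",
    "rank_candidates",
    "reports_to_frame",
]

TCC_RECEPTORS = frozenset({"α1G", "α1H", "α1I"})
LCC_RECEPTOR = "α1C"

TCC_SELECTIVE = "TCC_selective"
LCC_SELECTIVE = "LCC_selective"
DUAL_BLOCKER = "dual_blocker"
NON_BINDER = "non_binder"
CATEGORIES = (TCC_SELECTIVE, DUAL_BLOCKER, LCC_SELECTIVE, NON_BINDER)

GAS_CONSTANT_KCAL = 0.001986  # kcal·mol⁻¹·K⁻¹
BODY_TEMPERATURE_K = 310.0

_MISSING_TOKENS = {"", "N/A", "NA", "NAN", "NONE", "NULL"}
_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


class SelectivityError(ValueError):
    """Malformed docking table or report request."""


@dataclass(frozen=True)
class DockingRecord:
    """One compound × receptor docking outcome."""

    compound: str
    receptor: str
    delta_g: float | None  # kcal/mol; None = no predicted binding
    binding_domain: int | None = None  # 1-4
    binding_residue: ResidueLabel | None = None
    bond_type: str = "none"  # hydrogen | halogen | none

    def __post_init__(self) -> None:
        if self.binding_domain is not None and self.binding_domain not in (1, 2, 3, 4):
            raise SelectivityError(
                f"{self.compound}/{self.receptor}: binding domain must be 1-4"
            )
        if self.bond_type not in ("hydrogen", "halogen", "none"):
            raise SelectivityError(
                f"{self.compound}/{self.receptor}: bad bond type {self.bond_type!r}"
            )


@dataclass(frozen=True)
class BindingAffinity:
    """Dissociation constant derived from a docking free energy.

    Under the default ``thermodynamic`` convention Kd = exp(ΔG/(R·T)),
    so a more negative ΔG gives a smaller (tighter) Kd and ΔG = 0 gives
    Kd = 1 M.  The ``printed`` convention evaluates Kd = exp(−ΔG/(R·T))
    — the literal typeset formula, whose value is the reciprocal — and
    is retained for traceability.  The convention used is always carried
    in the record.
    """

    kd: float  # molar
    delta_g: float  # kcal/mol
    temperature: float  # K
    gas_constant: float  # kcal·mol⁻¹·K⁻¹
    convention: str


def delta_g_to_kd(
    delta_g: float,
    temperature: float = BODY_TEMPERATURE_K,
    gas_constant: float = GAS_CONSTANT_KCAL,
    convention: str = "thermodynamic",
) -> BindingAffinity:
    """Convert a docking ΔG (kcal/mol) to a dissociation constant (M)."""
    if not temperature > 0:
        raise SelectivityError("temperature must be positive")
    if convention not in ("thermodynamic", "printed"):
        raise SelectivityError(f"unknown Kd convention {convention!r}")
    exponent = delta_g / (gas_constant * temperature)
    if convention == "printed":
        exponent = -exponent
    return BindingAffinity(
        kd=math.exp(exponent),
        delta_g=delta_g,
        temperature=temperature,
        gas_constant=gas_constant,
        convention=convention,
    )


def _parse_missing(token) -> str | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    text = str(token).strip()
    return None if text.upper() in _MISSING_TOKENS else text


def _parse_domain(token) -> int | None:
    text = _parse_missing(token)
    if text is None:
        return None
    if text.upper() in _ROMAN:
        return _ROMAN[text.upper()]
    try:
        return int(text)
    except ValueError as exc:
        raise SelectivityError(f"cannot parse binding domain {token!r}") from exc


def load_docking_table(
    source: str | Path | io.IOBase | pd.DataFrame,
    positive_dg_warning: float = 0.0,
) -> list[DockingRecord]:
    """Read a docking table CSV into :class:`DockingRecord` rows.

    Columns: compound, receptor, delta_g_kcal_mol, binding_domain,
    binding_residue, bond_type (the last three optional).  ``N/A`` marks
    missing values; binding domains may be Roman or Arabic numerals.
    Unknown receptor names and ΔG above ``positive_dg_warning`` raise
    warnings (not errors); malformed numeric fields raise.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if df.empty:
        return []
    for col in ("compound", "receptor", "delta_g_kcal_mol"):
        if col not in df.columns:
            raise SelectivityError(f"docking table missing column {col!r}")
    records: list[DockingRecord] = []
    for idx, rec in df.iterrows():
        compound = str(rec["compound"]).strip()
        raw_receptor = str(rec["receptor"]).strip()
        try:
            receptor = normalize_channel(raw_receptor)
        except SequenceError:
            warnings.warn(f"row {idx}: unknown receptor {raw_receptor!r} kept as-is")
            receptor = raw_receptor
        dg_text = _parse_missing(rec["delta_g_kcal_mol"])
        if dg_text is None:
            delta_g = None
        else:
            try:
                delta_g = float(dg_text)
            except ValueError as exc:
                raise SelectivityError(
                    f"row {idx} ({compound}/{receptor}): bad ΔG {dg_text!r}"
                ) from exc
            if delta_g > positive_dg_warning:
                warnings.warn(
                    f"row {idx} ({compound}/{receptor}): "
                    f"ΔG = {delta_g} kcal/mol is not a favourable binding energy"
                )
        residue_text = _parse_missing(rec.get("binding_residue"))
        records.append(
            DockingRecord(
                compound=compound,
                receptor=receptor,
                delta_g=delta_g,
                binding_domain=_parse_domain(rec.get("binding_domain")),
                binding_residue=(
                    ResidueLabel.parse(residue_text) if residue_text else None
                ),
                bond_type=_parse_missing(rec.get("bond_type")) or "none",
            )
        )
    return records


def _binds(record: DockingRecord, domains: frozenset[int] | set[int],
           threshold: float | None) -> bool:
    if record.delta_g is None:
        return False
    if threshold is not None and record.delta_g > threshold:
        return False
    return record.binding_domain in domains


def classify_selectivity(
    records: Sequence[DockingRecord],
    tcc_domains: Iterable[int] = (1, 4),
    lcc_domains: Iterable[int] = (3, 4),
    binding_threshold: float | None = None,
) -> str:
    """Category of one compound from its per-receptor docking rows.

    *binds TCC*: any of α1G/α1H/α1I has a present ΔG (≤ threshold, when
    one is set) with its pose in ``tcc_domains``.  *binds LCC*: α1C has
    a present ΔG with its pose in ``lcc_domains``.  The four outcomes
    partition every input; row order is irrelevant.
    """
    if not records:
        raise SelectivityError("no docking records supplied")
    compounds = {r.compound for r in records}
    if len(compounds) > 1:
        raise SelectivityError(f"records mix compounds {sorted(compounds)}")
    tcc_set, lcc_set = set(tcc_domains), set(lcc_domains)
    binds_tcc = any(
        _binds(r, tcc_set, binding_threshold)
        for r in records
        if r.receptor in TCC_RECEPTORS
    )
    binds_lcc = any(
        _binds(r, lcc_set, binding_threshold)
        for r in records
        if r.receptor == LCC_RECEPTOR
    )
    if binds_tcc and binds_lcc:
        return DUAL_BLOCKER
    if binds_tcc:
        return TCC_SELECTIVE
    if binds_lcc:
        return LCC_SELECTIVE
    return NON_BINDER


@dataclass(frozen=True)
class SelectivityReport:
    """Per-compound selectivity call with supporting evidence."""

    compound: str
    category: str
    best_tcc_delta_g: float | None = None
    best_tcc_receptor: str | None = None
    best_tcc_kd: float | None = None
    lcc_delta_g: float | None = None
    binding_domains: Mapping[str, int | None] = field(default_factory=dict)
    kd_convention: str = "thermodynamic"
    rank: int | None = None
    properties_available: bool | None = None
    beats_references_affinity: bool | None = None
    beats_references_logp: bool | None = None
    beats_references_qed: bool | None = None


def classify_table(
    records: Sequence[DockingRecord],
    tcc_domains: Iterable[int] = (1, 4),
    lcc_domains: Iterable[int] = (3, 4),
    binding_threshold: float | None = None,
    convention: str = "thermodynamic",
) -> list[SelectivityReport]:
    """Classify every compound in a docking table; reports sorted by id."""
    by_compound: dict[str, list[DockingRecord]] = {}
    for r in records:
        by_compound.setdefault(r.compound, []).append(r)
    reports = []
    for compound in sorted(by_compound):
        rows = by_compound[compound]
        category = classify_selectivity(rows, tcc_domains, lcc_domains, binding_threshold)
        tcc_rows = [
            r for r in rows if r.receptor in TCC_RECEPTORS and r.delta_g is not None
        ]
        best = min(tcc_rows, key=lambda r: r.delta_g, default=None)
        lcc_dg = next(
            (r.delta_g for r in rows if r.receptor == LCC_RECEPTOR), None
        )
        reports.append(
            SelectivityReport(
                compound=compound,
                category=category,
                best_tcc_delta_g=best.delta_g if best else None,
                best_tcc_receptor=best.receptor if best else None,
                best_tcc_kd=(
                    delta_g_to_kd(best.delta_g, convention=convention).kd
                    if best
                    else None
                ),
                lcc_delta_g=lcc_dg,
                binding_domains={r.receptor: r.binding_domain for r in rows},
                kd_convention=convention,
            )
        )
    return reports


_CATEGORY_ORDER = {c: i for i, c in enumerate(CATEGORIES)}


def rank_candidates(
    reports: Sequence[SelectivityReport],
    properties: Sequence | None = None,
    reference_compounds: Iterable[str] | None = None,
) -> list[SelectivityReport]:
    """Order reports for triage and compare candidates against references.

    TCC-selective compounds come first, sorted by best T-type ΔG
    ascending (more negative = better); ties break on higher QED, then
    lower logP.  Remaining categories follow in dual/LCC/non-binder
    order.  ``properties`` is a sequence of objects with id/logp/qed
    attributes (e.g. :class:`tccsel.properties.CompoundRecord`); each
    ranked candidate is flagged for whether it beats *every* reference
    compound on affinity (ΔG), logP (lower) and QED (higher).  Compounds
    without a property row are still ranked but flagged unfiltered.
    """
    props = {p.id: p for p in (properties or [])}
    if reference_compounds is None:
        reference_compounds = [
            p.id for p in (properties or []) if getattr(p, "role", None) == "reference"
        ]
    ref_ids = set(reference_compounds)
    by_id = {r.compound: r for r in reports}
    ref_dgs = [
        by_id[i].best_tcc_delta_g
        for i in ref_ids
        if i in by_id and by_id[i].best_tcc_delta_g is not None
    ]
    ref_logps = [props[i].logp for i in ref_ids if i in props]
    ref_qeds = [props[i].qed for i in ref_ids if i in props]

    def annotate(rep: SelectivityReport) -> SelectivityReport:
        if rep.compound in ref_ids:
            return rep
        p = props.get(rep.compound)
        beats_aff = (
            None
            if rep.best_tcc_delta_g is None
            else all(rep.best_tcc_delta_g < dg for dg in ref_dgs)
        )
        return replace(
            rep,
            properties_available=p is not None,
            beats_references_affinity=beats_aff,
            beats_references_logp=(
                all(p.logp < x for x in ref_logps) if p is not None else None
            ),
            beats_references_qed=(
                all(p.qed > x for x in ref_qeds) if p is not None else None
            ),
        )

    def sort_key(rep: SelectivityReport):
        p = props.get(rep.compound)
        dg = rep.best_tcc_delta_g
        return (
            _CATEGORY_ORDER[rep.category],
            dg if dg is not None else math.inf,
            -(p.qed if p is not None else -math.inf),
            p.logp if p is not None else math.inf,
            rep.compound,
        )

    ordered = sorted((annotate(r) for r in reports), key=sort_key)
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def reports_to_frame(reports: Sequence[SelectivityReport]) -> pd.DataFrame:
    """Flatten reports for CSV/JSON export."""
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "compound": r.compound,
                "category": r.category,
                "best_tcc_delta_g_kcal_mol": r.best_tcc_delta_g,
                "best_tcc_receptor": r.best_tcc_receptor,
                "best_tcc_kd_M": r.best_tcc_kd,
                "kd_convention": r.kd_convention,
                "lcc_delta_g_kcal_mol": r.lcc_delta_g,
                "properties_available": r.properties_available,
                "beats_references_affinity": r.beats_references_affinity,
                "beats_references_logp": r.beats_references_logp,
                "beats_references_qed": r.beats_references_qed,
            }
            for r in reports
        ]
    )
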