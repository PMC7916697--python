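"""Drug-likeness descriptors and the reference-blocker comparison filter.

Candidate T-type blocker structures are profiled with three standard
descriptors:

* **logP** — Crippen–Wildman atom-contribution octanol/water partition
  estimate (lipophilicity; lower is generally friendlier).
* **SAS** — Ertl–Schuffenhauer synthetic accessibility score, 1 (easy)
  to 10 (hard), from fragment contributions plus complexity penalties.
* **QED** — Bickerton quantitative estimate of drug-likeness, a 0–1
  desirability product over eight molecular properties.

The screening filter compares a candidate against a panel of reference
blockers: by default the candidate must have strictly lower logP than
every reference and strictly higher QED than every reference.  SAS is
reported alongside but not enforced by default — for the compound panel
this package ships, the candidates' SAS values run *above* the reference
blockers', so an "easier to make than every marketed blocker" criterion
would empty the candidate list; a strict three-criterion mode is
available for cohorts where it is meaningful.

Descriptors are computed on the neutral input structure as drawn; no
pH-dependent protonation state is applied.
"""

from __future__ import annotations

import io
import math
import os
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, QED, RDConfig

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, resolved from the install)

__all__ = [
    "PropertyError",
    "StructureError",
    "CompoundRecord",
    "FilterResult",
    "compute_properties",
    "reference_filter",
    "load_property_table",
    "load_smiles",
    "rdkit_version",
]


class PropertyError(ValueError):
    """Invalid property value or table."""


class StructureError(PropertyError):
    """A structure could not be parsed."""


def rdkit_version() -> str:
    import rdkit

    return rdkit.__version__


@dataclass(frozen=True)
class CompoundRecord:
    """A compound with its drug-likeness profile.

    ``structure`` (SMILES) is optional when the three descriptor values
    are supplied directly, as for tabulated panels.
    """

    id: str
    logp: float
    sas: float
    qed: float
    structure: str | None = None
    role: str = "candidate"  # candidate | reference

    def __post_init__(self) -> None:
        if not self.id:
            raise PropertyError("compound id must be non-empty")
        if not math.isfinite(self.logp):
            raise PropertyError(f"{self.id}: logP must be finite")
        if not 0.0 < self.qed <= 1.0:
            raise PropertyError(f"{self.id}: QED must lie in (0, 1], got {self.qed}")
        if not 1.0 <= self.sas <= 10.0:
            raise PropertyError(f"{self.id}: SAS must lie in [1, 10], got {self.sas}")
        if self.role not in ("candidate", "reference"):
            raise PropertyError(f"{self.id}: role must be candidate or reference")


def compute_properties(structure: str, id: str | None = None,
                       role: str = "candidate") -> CompoundRecord:
    """Compute logP / SAS / QED for a SMILES string.

    Values come from the installed RDKit (Crippen logP, contrib Ertl
    SA_Score, QED); record them together with :func:`rdkit_version`
    when comparing against numbers produced elsewhere, since descriptor
    parameterisations drift between releases.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"cannot parse SMILES {structure!r}")
    return CompoundRecord(
        id=id or structure,
        structure=structure,
        logp=Crippen.MolLogP(mol),
        sas=sascorer.calculateScore(mol),
        qed=QED.qed(mol),
        role=role,
    )


@dataclass(frozen=True)
class FilterResult:
    """Per-criterion outcome of the reference comparison (strict inequalities)."""

    compound: str
    logp_below_all: bool
    qed_above_all: bool
    sas_below_all: bool
    enforced: tuple[str, ...]
    passed: bool


def reference_filter(
    candidate: CompoundRecord,
    references: Sequence[CompoundRecord],
    criteria: Iterable[str] = ("logp", "qed"),
) -> FilterResult:
    """Compare one candidate against every reference blocker.

    All comparisons are strict — ties fail.  ``criteria`` selects which
    of ``logp`` (lower than all), ``qed`` (higher than all) and ``sas``
    (lower than all) must hold for an overall pass; all three booleans
    are always reported.
    """
    if not references:
        raise PropertyError("reference set must be non-empty")
    enforced = tuple(criteria)
    unknown = set(enforced) - {"logp", "qed", "sas"}
    if unknown:
        raise PropertyError(f"unknown filter criteria {sorted(unknown)}")
    outcome = {
        "logp": all(candidate.logp < r.logp for r in references),
        "qed": all(candidate.qed > r.qed for r in references),
        "sas": all(candidate.sas < r.sas for r in references),
    }
    return FilterResult(
        compound=candidate.id,
        logp_below_all=outcome["logp"],
        qed_above_all=outcome["qed"],
        sas_below_all=outcome["sas"],
        enforced=enforced,
        passed=all(outcome[c] for c in enforced),
    )


def load_property_table(source: str | Path | io.IOBase | pd.DataFrame) -> list[CompoundRecord]:
    """Read a property CSV (id, logp, sas, qed[, role[, structure]])."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if df.empty:
        return []
    for col in ("id", "logp", "sas", "qed"):
        if col not in df.columns:
            raise PropertyError(f"property table missing column {col!r}")
    records = []
    for idx, rec in df.iterrows():
        try:
            records.append(
                CompoundRecord(
                    id=str(rec["id"]).strip(),
                    logp=float(rec["logp"]),
                    sas=float(rec["sas"]),
                    qed=float(rec["qed"]),
                    structure=(str(rec["structure"]).strip() or None)
                    if "structure" in df.columns
                    else None,
                    role=(str(rec.get("role", "")).strip() or "candidate"),
                )
            )
        except (PropertyError, ValueError) as exc:
            raise PropertyError(f"property table row {idx}: {exc}") from exc
    return records


def load_smiles(source: str | Path | io.IOBase) -> list[CompoundRecord]:
    """Compute properties for a ``SMILES<TAB>id`` file (one compound per line)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    records = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        cid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else smiles
        try:
            records.append(compute_properties(smiles, id=cid))
        except StructureError as exc:
            raise StructureError(f"line {ln}: {exc}") from exc
    return records
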