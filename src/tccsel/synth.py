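"""Synthetic docking cohorts with known ground truth, plus packaged panels.

The docking and property tables this package analyses normally come from
external modelling pipelines (homology modelling + pose docking).  For
testing the triage logic end to end, :func:`generate_cohort` fabricates
cohorts whose class composition is known by construction:

* **TCC_selective** compounds get a present ΔG on every T-type receptor
  (α1G/α1H/α1I) with the pose in domain I or IV, and no α1C binding;
* **dual_blocker** compounds additionally bind α1C in domain III or IV;
* **non_binder** compounds have every ΔG missing.

ΔG values are Gaussian draws truncated below 0 (favourable energies
only; the packaged panel spans −5.4 to −8.1 kcal/mol) — they emulate the
*shape* of a docking table, not any scoring physics.  Property values
are class-conditional uniform draws calibrated to the packaged panel's
extrema.  A single ``numpy`` generator seeded from ``CohortSpec.seed``
drives every draw, so identical specs give byte-identical tables.

The module also exposes the packaged study tables (docking panel,
property panel, pore-segment alignment, reduced-filter energies) with
checksum verification.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .properties import CompoundRecord, load_property_table
from .selectivity import DockingRecord, load_docking_table
from .sequences import SegmentSequence, load_alignment

__all__ = [
    "SynthError",
    "FixtureIntegrityError",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "fixture_path",
    "table1_fixture",
    "table2_fixture",
    "table3_fixture",
    "table4_fixture",
]

RECEPTORS = ("α1C", "α1G", "α1H", "α1I")

_FIXTURE_SHA256 = {
    "table1_reduced.tsv": "97c2ffbb0bb23e89b6e1fb2e39706e79581447a54a571522fe2f48c831ef907d",
    "table2_docking.csv": "b7f709bfb8dfc5cc3270d05e9ba1dda0edfd2b1a4e502e8ac1567c5994b75858",
    "table3_properties.csv": "6070fb6e0403978405ea07f1f503876d274f8e8e4d181dbb94d451ae5c048e8d",
    "table4_alignment.tsv": "e63dbbf3e0c8c36fadf0fd0d499a32f6708e67f2035ed96d504ab26705795c14",
}


class SynthError(ValueError):
    """Invalid cohort specification."""


class FixtureIntegrityError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


def fixture_path(name: str) -> Path:
    """Path of a packaged data file, verified against its checksum."""
    if name not in _FIXTURE_SHA256:
        raise KeyError(f"unknown fixture {name!r}")
    path = Path(str(resources.files("tccsel").joinpath("data", name)))
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} != expected {_FIXTURE_SHA256[name]}"
        )
    return path


def table1_fixture() -> pd.DataFrame:
    """Reduced-filter P-loop sequences with their published BEM energies."""
    return pd.read_csv(fixture_path("table1_reduced.tsv"), sep="\t")


def table2_fixture() -> list[DockingRecord]:
    """The 24-row phenylalkylamine docking panel (6 compounds × 4 receptors)."""
    return load_docking_table(fixture_path("table2_docking.csv"))


def table3_fixture() -> list[CompoundRecord]:
    """The 17-row compound property panel (4 reference blockers + 13 candidates)."""
    return load_property_table(fixture_path("table3_properties.csv"))


def table4_fixture() -> list[SegmentSequence]:
    """The α1C/α1G pore-segment alignment (2 channels × 4 domains × 3 segments)."""
    return load_alignment(fixture_path("table4_alignment.tsv"))


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic docking + property cohort.

    Class fractions: ``fraction_tcc_selective`` and
    ``fraction_non_binder`` must sum to ≤ 1; the remainder are dual
    blockers.  Counts are rounded per class (TCC-selective first), so a
    fraction of 0.3 on n = 100 yields exactly 30 labelled compounds.
    ``missingness_noise`` is the probability that any present ΔG is
    dropped to N/A after generation, emulating docking runs that return
    no pose.  Property ranges are uniform class-conditional bounds
    (logP, SAS, QED); defaults bracket the packaged panel's extrema.
    """

    n_compounds: int
    fraction_tcc_selective: float = 0.3
    fraction_non_binder: float = 0.2
    tcc_dg_mean: float = -7.5
    tcc_dg_sd: float = 0.5
    dual_tcc_dg_mean: float = -7.0
    dual_tcc_dg_sd: float = 0.5
    dual_lcc_dg_mean: float = -6.1
    dual_lcc_dg_sd: float = 0.4
    missingness_noise: float = 0.0
    logp_range: tuple[float, float] = (3.7, 6.3)
    sas_range: tuple[float, float] = (3.1, 5.2)
    qed_range: tuple[float, float] = (0.24, 0.64)
    dominant_candidate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 0:
            raise SynthError("n_compounds must be >= 0")
        for frac in (self.fraction_tcc_selective, self.fraction_non_binder):
            if not 0.0 <= frac <= 1.0:
                raise SynthError("class fractions must lie in [0, 1]")
        if self.fraction_tcc_selective + self.fraction_non_binder > 1.0 + 1e-12:
            raise SynthError("class fractions must sum to <= 1")
        for sd in (self.tcc_dg_sd, self.dual_tcc_dg_sd, self.dual_lcc_dg_sd):
            if not sd > 0:
                raise SynthError("ΔG standard deviations must be positive")
        if not 0.0 <= self.missingness_noise <= 1.0:
            raise SynthError("missingness_noise must lie in [0, 1]")
        for lo, hi in (self.logp_range, self.sas_range, self.qed_range):
            if not lo <= hi:
                raise SynthError("property ranges must be (low, high)")

    @property
    def class_counts(self) -> dict[str, int]:
        n_tcc = int(round(self.n_compounds * self.fraction_tcc_selective))
        n_non = min(
            int(round(self.n_compounds * self.fraction_non_binder)),
            self.n_compounds - n_tcc,
        )
        return {
            "TCC_selective": n_tcc,
            "non_binder": n_non,
            "dual_blocker": self.n_compounds - n_tcc - n_non,
        }


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated docking table, property table and ground-truth labels."""

    docking: pd.DataFrame
    properties: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec = field(repr=False)

    def write(self, prefix: str | Path) -> dict[str, Path]:
        """Write docking.csv / properties.csv / truth.csv under a prefix."""
        prefix = Path(prefix)
        prefix.mkdir(parents=True, exist_ok=True)
        paths = {
            "docking": prefix / "docking.csv",
            "properties": prefix / "properties.csv",
            "truth": prefix / "truth.csv",
        }
        self.docking.to_csv(paths["docking"], index=False)
        self.properties.to_csv(paths["properties"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian draw constrained to negative energies (rejection sampling)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x < 0:
            return float(x)
    raise SynthError(
        f"could not draw a negative ΔG from N({mean}, {sd}); "
        "check the distribution parameters"
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort with known per-compound selectivity classes.

    The docking table has one row per compound × receptor (missing
    energies included as ``N/A`` rows, as in real panels); the truth
    table records each compound's generating class.  With
    ``dominant_candidate=True`` the first compound is forced
    TCC-selective with an off-scale ΔG and best-in-cohort properties, as
    a planted positive control for ranking.
    """
    rng = np.random.default_rng(spec.seed)
    counts = spec.class_counts
    labels = (
        ["TCC_selective"] * counts["TCC_selective"]
        + ["dual_blocker"] * counts["dual_blocker"]
        + ["non_binder"] * counts["non_binder"]
    )
    if spec.dominant_candidate and labels:
        labels[0] = "TCC_selective"

    docking_rows: list[dict] = []
    property_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i, label in enumerate(labels):
        cid = f"SYN-{i:04d}"
        dominant = spec.dominant_candidate and i == 0
        per_receptor: dict[str, tuple[float | None, int | None]] = {}
        if label == "non_binder":
            for receptor in RECEPTORS:
                per_receptor[receptor] = (None, None)
        else:
            if label == "dual_blocker":
                lcc_dg = _truncated_normal(rng, spec.dual_lcc_dg_mean, spec.dual_lcc_dg_sd)
                per_receptor["α1C"] = (lcc_dg, int(rng.choice([3, 4])))
                tcc_mean, tcc_sd = spec.dual_tcc_dg_mean, spec.dual_tcc_dg_sd
            else:
                per_receptor["α1C"] = (None, None)
                tcc_mean, tcc_sd = spec.tcc_dg_mean, spec.tcc_dg_sd
            for receptor in RECEPTORS[1:]:
                dg = (
                    spec.tcc_dg_mean - 20.0 * spec.tcc_dg_sd
                    if dominant
                    else _truncated_normal(rng, tcc_mean, tcc_sd)
                )
                per_receptor[receptor] = (dg, int(rng.choice([1, 4])))
        # missingness noise: docking runs that return no pose
        for receptor in RECEPTORS:
            dg, domain = per_receptor[receptor]
            if dg is not None and spec.missingness_noise > 0:
                if rng.random() < spec.missingness_noise:
                    dg, domain = None, None
            docking_rows.append(
                {
                    "compound": cid,
                    "receptor": receptor,
                    "delta_g_kcal_mol": "N/A" if dg is None else f"{dg:.4f}",
                    "binding_domain": "N/A" if domain is None else str(domain),
                    "binding_residue": "N/A",
                    "bond_type": "none",
                }
            )
        if dominant:
            logp, sas, qed = spec.logp_range[0] - 1.0, spec.sas_range[0], 0.95
        else:
            logp = float(rng.uniform(*spec.logp_range))
            sas = float(rng.uniform(*spec.sas_range))
            qed = float(rng.uniform(*spec.qed_range))
        property_rows.append(
            {
                "id": cid,
                "logp": f"{logp:.4f}",
                "sas": f"{sas:.4f}",
                "qed": f"{qed:.4f}",
                "role": "candidate",
            }
        )
        truth_rows.append({"compound": cid, "true_class": label})

    columns_d = [
        "compound",
        "receptor",
        "delta_g_kcal_mol",
        "binding_domain",
        "binding_residue",
        "bond_type",
    ]
    return SyntheticCohort(
        docking=pd.DataFrame(docking_rows, columns=columns_d),
        properties=pd.DataFrame(
            property_rows, columns=["id", "logp", "sas", "qed", "role"]
        ),
        truth=pd.DataFrame(truth_rows, columns=["compound", "true_class"]),
        spec=spec,
    )
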