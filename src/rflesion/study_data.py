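"""Reference measurement tables from the ex vivo ablation study.

The study ablated porcine ventricular myocardium at 5 catheter contact
angles x 8 contact forces, 6 replicates per condition, and reported mean
+/- SD lesion area (mm^2), mean +/- SD lesion depth (mm), and the
dimensionless ratio of lesion area to catheter contact area for each of
the 40 conditions.  Those printed tables are the package's only
real-data ground truth; they are shipped as plain CSV fixtures,
transcribed digit for digit and guarded by SHA-256 checksums.

The catheter contact area itself was measured in a companion ink-transfer
experiment and enters only through the printed area/contact ratios; it is
recovered here as ``contact_area = mean lesion area / ratio`` (a ratio of
means — the contact-area replicates were not paired with the ablation
replicates).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: Catheter contact angles used in the study, degrees from the tissue plane
#: (0 = catheter parallel to the surface, 90 = perpendicular).
ANGLES_DEG: tuple[int, ...] = (0, 30, 45, 60, 90)

#: Catheter contact forces used in the study, gram-force.
FORCES_GF: tuple[int, ...] = (2, 4, 6, 10, 15, 20, 30, 40)

#: Replicates per (angle, force) condition.
REPLICATES: int = 6

_FIXTURES: dict[str, tuple[str, str]] = {
    "lesion_area": (
        "lesion_area.csv",
        "2b63a50d887f52f94265abb492410472c75706ba6f9172f84da8b14e32f336ca",
    ),
    "lesion_depth": (
        "lesion_depth.csv",
        "7cf44f9d3552fb9e864f64759a4546794fa6cce438fc8259f69af2317d5cbd73",
    ),
    "ratio": (
        "area_contact_ratio.csv",
        "34d44e308ef37ca3c1797c09fe4695d440bacab655f7b0f97e2b2bc5120f155e",
    ),
}


class FixtureError(RuntimeError):
    """A packaged data fixture is missing, corrupt, or tampered with."""


@dataclass(frozen=True, order=True)
class AblationCondition:
    """One (contact angle, contact force) cell of the 5 x 8 study grid."""

    angle_deg: int
    force_gf: int

    def __post_init__(self) -> None:
        if self.angle_deg not in ANGLES_DEG:
            raise ValueError(f"angle_deg {self.angle_deg} not in {ANGLES_DEG}")
        if self.force_gf not in FORCES_GF:
            raise ValueError(f"force_gf {self.force_gf} not in {FORCES_GF}")


@dataclass(frozen=True)
class CellSummary:
    """Per-condition summary statistics (mean, sample SD, replicate count).

    ``sd`` and ``n`` are NaN/0 for quantities printed as single values
    (the area/contact ratios and the derived contact areas).
    """

    condition: AblationCondition
    mean: float
    sd: float = float("nan")
    n: int = 0


@dataclass(frozen=True)
class ConditionTable:
    """A complete 40-cell grid of one measured quantity.

    quantity_label is one of ``lesion_area`` (mm^2), ``lesion_depth`` (mm),
    ``ratio`` (dimensionless) or ``contact_area`` (mm^2, derived).
    """

    cells: Mapping[AblationCondition, CellSummary]
    quantity_label: str

    def __post_init__(self) -> None:
        expected = {
            AblationCondition(a, f) for a in ANGLES_DEG for f in FORCES_GF
        }
        if set(self.cells) != expected:
            missing = sorted(expected - set(self.cells))
            extra = sorted(set(self.cells) - expected)
            raise FixtureError(
                f"{self.quantity_label}: bad condition grid "
                f"(missing {missing}, extra {extra})"
            )

    def cell(self, angle_deg: int, force_gf: int) -> CellSummary:
        return self.cells[AblationCondition(angle_deg, force_gf)]

    def conditions(self) -> list[AblationCondition]:
        """All 40 conditions in sorted (angle, force) order."""
        return sorted(self.cells)

    def means(self) -> np.ndarray:
        """Cell means in sorted condition order (length 40)."""
        return np.array([self.cells[c].mean for c in self.conditions()])

    def sds(self) -> np.ndarray:
        return np.array([self.cells[c].sd for c in self.conditions()])

    def angles(self) -> np.ndarray:
        return np.array([c.angle_deg for c in self.conditions()], dtype=float)

    def forces(self) -> np.ndarray:
        return np.array([c.force_gf for c in self.conditions()], dtype=float)

    def row(self, angle_deg: int) -> np.ndarray:
        """Means for one contact angle across the 8 forces, ascending force."""
        return np.array(
            [self.cells[AblationCondition(angle_deg, f)].mean for f in FORCES_GF]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per condition (angle_deg, force_gf, mean, sd, n)."""
        recs = [
            {
                "angle_deg": c.angle_deg,
                "force_gf": c.force_gf,
                "mean": self.cells[c].mean,
                "sd": self.cells[c].sd,
                "n": self.cells[c].n,
            }
            for c in self.conditions()
        ]
        return pd.DataFrame.from_records(recs)

    def __iter__(self) -> Iterator[CellSummary]:
        return iter(self.cells[c] for c in self.conditions())


def fixture_sha256(name: str) -> str:
    """SHA-256 of a packaged fixture file (``lesion_area`` etc.)."""
    filename, _ = _FIXTURES[name]
    data = resources.files("rflesion.data").joinpath(filename).read_bytes()
    return hashlib.sha256(data).hexdigest()


def verify_fixtures() -> dict[str, str]:
    """Check every fixture against its recorded checksum.

    Returns the name -> digest map; raises FixtureError on any mismatch.
    """
    digests = {}
    for name, (filename, expected) in _FIXTURES.items():
        got = fixture_sha256(name)
        if got != expected:
            raise FixtureError(
                f"fixture {filename} checksum mismatch: "
                f"expected {expected}, got {got}"
            )
        digests[name] = got
    return digests


def _load(name: str, quantity_label: str, with_sd: bool) -> ConditionTable:
    filename, expected = _FIXTURES[name]
    try:
        path = resources.files("rflesion.data").joinpath(filename)
        data = path.read_bytes()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise FixtureError(f"cannot read packaged fixture {filename}") from exc
    if hashlib.sha256(data).hexdigest() != expected:
        raise FixtureError(f"fixture {filename} failed its checksum")
    df = pd.read_csv(path)
    required = {"angle_deg", "force_gf", "mean"}
    if not required.issubset(df.columns):
        raise FixtureError(f"fixture {filename} lacks columns {required}")
    cells = {}
    for rec in df.itertuples(index=False):
        cond = AblationCondition(int(rec.angle_deg), int(rec.force_gf))
        mean = float(rec.mean)
        if not mean > 0:
            raise FixtureError(f"{filename}: non-positive mean in cell {cond}")
        if with_sd:
            sd, n = float(rec.sd), int(rec.n)
            if sd < 0 or n < 2:
                raise FixtureError(f"{filename}: bad sd/n in cell {cond}")
            cells[cond] = CellSummary(cond, mean, sd, n)
        else:
            cells[cond] = CellSummary(cond, mean)
    return ConditionTable(cells, quantity_label)


def load_lesion_area_table() -> ConditionTable:
    """Mean +/- SD ablated lesion area, mm^2, n = 6 per condition."""
    return _load("lesion_area", "lesion_area", with_sd=True)


def load_lesion_depth_table() -> ConditionTable:
    """Mean +/- SD maximum lesion depth, mm, n = 6 per condition."""
    return _load("lesion_depth", "lesion_depth", with_sd=True)


def load_ratio_table() -> ConditionTable:
    """Printed lesion-area / contact-area ratio, dimensionless, one value per cell."""
    return _load("ratio", "ratio", with_sd=False)


def recover_contact_area_table(
    area: ConditionTable, ratio: ConditionTable
) -> ConditionTable:
    """Invert the printed ratios to recover the catheter contact area grid.

    ratio = lesion_area / contact_area, so contact_area = mean lesion
    area / ratio (mm^2).  Ratios must be strictly positive.
    """
    if set(area.cells) != set(ratio.cells):
        raise ValueError("area and ratio tables cover different conditions")
    cells = {}
    for cond in area.conditions():
        r = ratio.cells[cond].mean
        if not r > 0:
            raise ValueError(f"non-positive ratio {r} in cell {cond}")
        cells[cond] = CellSummary(cond, area.cells[cond].mean / r)
    return ConditionTable(cells, "contact_area")
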