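"""Cohort CSV reading/validation, per-patient risk tables and chart rendering.

The cohort table holds one row per patient: paired surgeon/patient interface
judgments (percent), origin and destination altitudes (metres), travel mode,
visual acuity and the two 5-point Likert usability responses. Files are
UTF-8 comma-separated with a header row; percentages are stored as numbers
0-100. Unknown extra columns are preserved and passed through on write.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .agreement import PairedJudgments, summarize
from .atmosphere import ALTITUDE_MAX_M, ALTITUDE_MIN_M, AtmosphereModel
from .errors import CohortSchemaError, DomainError, RowValidationError
from .expansion import ExpansionResult, RiskPolicy, assess
from .geometry import VitreousGeometry

__all__ = [
    "PatientRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "cohort_risk_table",
    "render_interface_chart",
    "REQUIRED_COLUMNS",
    "DEFAULT_ORIGIN_ALTITUDE_M",
]

TravelMode = Literal["airplane", "train_highspeed", "train_ordinary", "car_bus"]

#: study-site altitude used when an origin column is absent (Guangzhou, 10 m)
DEFAULT_ORIGIN_ALTITUDE_M = 10.0

SCHEMA_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "surgeon_interface_pct",
    "patient_interface_pct",
    "origin_altitude_m",
    "destination_altitude_m",
    "travel_mode",
    "visual_acuity",
    "likert_item1",
    "likert_item2",
]
REQUIRED_COLUMNS = [c for c in SCHEMA_COLUMNS if c != "origin_altitude_m"]


class PatientRecord(BaseModel):
    """One validated cohort row."""

    model_config = ConfigDict(extra="allow", frozen=True)

    patient_id: str
    age: float = Field(ge=0, le=120)
    sex: Literal["M", "F"]
    surgeon_interface_pct: float = Field(ge=0, le=100)
    patient_interface_pct: float = Field(ge=0, le=100)
    origin_altitude_m: float = Field(
        default=DEFAULT_ORIGIN_ALTITUDE_M, ge=ALTITUDE_MIN_M, le=ALTITUDE_MAX_M
    )
    destination_altitude_m: float = Field(ge=ALTITUDE_MIN_M, le=ALTITUDE_MAX_M)
    travel_mode: TravelMode
    visual_acuity: str
    likert_item1: int = Field(ge=1, le=5)
    likert_item2: int = Field(ge=1, le=5)


@dataclass
class Cohort:
    """Ordered, validated patient records plus parse provenance."""

    records: list[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise DomainError("a cohort must contain at least one record")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DomainError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def paired_judgments(self) -> PairedJudgments:
        return PairedJudgments(
            surgeon=[r.surgeon_interface_pct for r in self.records],
            patient=[r.patient_interface_pct for r in self.records],
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {c: getattr(r, c) for c in SCHEMA_COLUMNS}
            row.update(r.model_extra or {})
            rows.append(row)
        return pd.DataFrame(rows)


def read_cohort(path) -> Cohort:
    """Read and validate a cohort CSV.

    The header is matched order-insensitively; ``origin_altitude_m`` is
    optional and defaults to the study-site altitude (10 m). Missing
    required columns raise :class:`CohortSchemaError`; rows failing
    validation raise :class:`RowValidationError` naming the 1-based data-row
    number and offending field. Extra columns are kept on the records.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"cohort file {path} is missing required column(s): {missing}"
        )
    records: list[PatientRecord] = []
    failures: list[tuple[int, str, str]] = []
    for i, raw in enumerate(df.to_dict(orient="records"), start=1):
        clean = {k: v for k, v in raw.items() if not _is_missing(v)}
        if "patient_id" in clean:
            clean["patient_id"] = str(clean["patient_id"])
        try:
            records.append(PatientRecord(**clean))
        except ValidationError as exc:
            for err in exc.errors():
                fld = str(err["loc"][0]) if err["loc"] else "<record>"
                failures.append((i, fld, err["msg"]))
    if failures:
        raise RowValidationError(failures)
    return Cohort(
        records=records,
        provenance={"source": str(path), "n_rows": len(records)},
    )


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (UTF-8, comma-separated, header row)."""
    cohort.to_dataframe().to_csv(path, index=False)


def cohort_risk_table(
    cohort: Cohort,
    geometry: VitreousGeometry,
    atmosphere: AtmosphereModel,
    policy: RiskPolicy,
) -> tuple[pd.DataFrame, dict]:
    """Per-patient expansion results for both judges, plus delta-V summaries.

    Returns a long-format DataFrame with one row per patient per judge
    (surgeon- and patient-judged interface heights) and a dict of
    median/min/max summaries of ``delta_v`` per judge.
    """
    rows = []
    for record in cohort.records:
        for judge, h in (
            ("surgeon", record.surgeon_interface_pct),
            ("patient", record.patient_interface_pct),
        ):
            try:
                result: ExpansionResult = assess(
                    h,
                    record.origin_altitude_m,
                    record.destination_altitude_m,
                    geometry,
                    atmosphere,
                    policy,
                )
            except DomainError as exc:
                raise DomainError(
                    f"patient {record.patient_id!r} ({judge} judgment): {exc}"
                ) from exc
            rows.append(
                {
                    "patient_id": record.patient_id,
                    "judge": judge,
                    "interface_pct": h,
                    "origin_altitude_m": record.origin_altitude_m,
                    "destination_altitude_m": record.destination_altitude_m,
                    "p1_kpa": result.p1,
                    "p2_kpa": result.p2,
                    "v1_ml": result.v1,
                    "v2_ml": result.v2,
                    "delta_v_ml": result.delta_v,
                    "risk_ratio": result.risk_ratio,
                    "category": result.category,
                }
            )
    table = pd.DataFrame(rows)
    summary = {
        judge: summarize(table.loc[table["judge"] == judge, "delta_v_ml"])
        for judge in ("surgeon", "patient")
    }
    return table, summary


def render_interface_chart(h_pct: float, path=None) -> str:
    """Render the patient-facing interface chart as SVG.

    Draws the circular field with a horizontal chord at ``h_pct`` percent of
    the vertical diameter measured down from the top; the gas region above
    the chord is shaded. Output is deterministic for a fixed input. Returns
    the SVG text; also writes it to ``path`` when given.
    """
    h_pct = float(h_pct)
    if not 0.0 <= h_pct <= 100.0:
        raise DomainError(
            f"interface height must lie in [0, 100] percent, got {h_pct!r}"
        )
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    with plt.rc_context({"svg.hashsalt": "oculogas"}):
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.add_patch(Circle((0, 0), 1.0, fill=False, lw=1.5, color="black"))
        h = h_pct / 100.0
        y_chord = 1.0 - 2.0 * h
        if h > 0:
            # shade the gas cap above the chord
            y = np.linspace(y_chord, 1.0, 200)
            x = np.sqrt(np.clip(1.0 - y**2, 0.0, None))
            ax.fill_betweenx(y, -x, x, color="0.75", zorder=0)
            if h < 1:
                half = float(np.sqrt(max(1.0 - y_chord**2, 0.0)))
                ax.plot([-half, half], [y_chord, y_chord], color="black", lw=1.2)
        ax.set_xlim(-1.1, 1.1)
        ax.set_ylim(-1.1, 1.1)
        ax.set_aspect("equal")
        ax.axis("off")
        buf = io.StringIO()
        fig.savefig(buf, format="svg", metadata={"Date": None})
        plt.close(fig)
    svg = buf.getvalue()
    if path is not None:
        Path(path).write_text(svg, encoding="utf-8")
    return svg
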