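"""Intensity-space gating of single cells into myeloid populations.

Mirrors a flow-cytometry workflow applied to image-derived cells: a
debris-exclusion master gate on Iba1 mean intensity defines "total cells";
a split gate on the microglial marker (P2RY12 or TMEM119) partitions total
cells into microglia (inside the region) and TAMs (outside); an optional
high/low gate on CD14 or CD163 — calibrated from negative-control epilepsy
tissue — adds a secondary cd_high/cd_low label.

Gate regions are 1-D half-open intervals [lo, hi) by default (a cell
sitting exactly on a threshold goes to the upper region); 2-D polygon
gates in (marker, Iba1) intensity space are supported for parity with
manually drawn gates.  Epilepsy and tumor tissue carry separate gate sets
because their staining patterns differ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, IntegrityError, SchemaError, ValidationError
from .segmentation import CellTable, intensity_column

__all__ = [
    "Interval",
    "PolygonRegion",
    "Gate",
    "GatingScheme",
    "PopulationCall",
    "apply_master_gate",
    "classify_microglia_tam",
    "derive_control_threshold",
    "ControlThreshold",
    "classify_high_low",
    "gate_report",
    "suggest_split_threshold",
]

TISSUE_SCOPES = ("tumor", "epilepsy", "all")
_TUMOR_TISSUES = ("meningioma", "low_grade", "grade_iv")


@dataclass(frozen=True)
class Interval:
    """Closed-left, open-right intensity interval [lo, hi)."""

    lo: float
    hi: float = math.inf

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"interval requires lo < hi, got [{self.lo}, {self.hi})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.lo) & (v < self.hi)


@dataclass(frozen=True)
class PolygonRegion:
    """Simple polygon in 2-D intensity space; boundary points are inside."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValidationError("polygon needs at least 3 vertices")
        if not self._shapely().is_simple:
            raise ValidationError("polygon must be simple (non-self-intersecting)")

    def _shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        from shapely import covers, points

        poly = self._shapely()
        pts = points(np.asarray(xy, dtype=float))
        return covers(poly, pts)


@dataclass(frozen=True)
class Gate:
    """A named region in 1-D or 2-D intensity space, scoped to a tissue class."""

    name: str
    markers: tuple[str, ...]
    region: Interval | PolygonRegion
    tissue_scope: str = "all"

    def __post_init__(self) -> None:
        if self.tissue_scope not in TISSUE_SCOPES:
            raise ValidationError(f"tissue_scope must be one of {TISSUE_SCOPES}")
        ndim = 1 if isinstance(self.region, Interval) else 2
        if len(self.markers) != ndim:
            raise ValidationError(
                f"gate {self.name!r}: {ndim}-D region needs {ndim} marker(s), got {self.markers}"
            )

    def membership(self, table: CellTable) -> np.ndarray:
        if isinstance(self.region, Interval):
            return self.region.contains(table.intensities(self.markers[0]).to_numpy())
        xy = np.column_stack(
            [table.intensities(m).to_numpy() for m in self.markers]
        )
        return self.region.contains(xy)


def _scope_of(tissue_type: str) -> str:
    return "epilepsy" if tissue_type == "epilepsy" else "tumor"


@dataclass
class GatingScheme:
    """Hierarchy of gates: master (Iba1 debris exclusion), microglia/TAM split,
    optional CD14/CD163 high/low gate — each with per-tissue-scope variants.

    ``master``/``split``/``highlow`` map tissue scope ("tumor", "epilepsy",
    "all") to a Gate; lookup prefers the exact scope and falls back to "all".
    """

    master: dict[str, Gate] = field(default_factory=dict)
    split: dict[str, Gate] = field(default_factory=dict)
    highlow: dict[str, Gate] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.master:
            raise ValidationError("scheme needs a master gate")
        if not self.split:
            raise ValidationError("scheme needs a microglia/TAM split gate")
        for role, gates in (("master", self.master), ("split", self.split), ("highlow", self.highlow)):
            for scope, gate in gates.items():
                if scope != gate.tissue_scope:
                    raise ValidationError(
                        f"{role} gate {gate.name!r} keyed under {scope!r} but scoped {gate.tissue_scope!r}"
                    )

    @classmethod
    def from_thresholds(
        cls,
        master_iba1_min: float,
        split_threshold: float,
        split_marker: str,
        highlow_threshold: float | None = None,
        highlow_marker: str | None = None,
        tissue_scope: str = "all",
        provenance: dict | None = None,
    ) -> "GatingScheme":
        """Build the default 1-D threshold scheme.

        Master gate: Iba1 mean >= master_iba1_min.  Split gate: microglial
        marker mean >= split_threshold -> microglia.  High/low gate: CD
        marker mean >= highlow_threshold -> cd_high.
        """
        master = Gate("total_cells", ("Iba1",), Interval(master_iba1_min), tissue_scope)
        split = Gate("microglia", (split_marker,), Interval(split_threshold), tissue_scope)
        scheme = cls(
            master={tissue_scope: master},
            split={tissue_scope: split},
            provenance=provenance or {},
        )
        if highlow_threshold is not None:
            if highlow_marker is None:
                raise ValidationError("highlow_threshold given without highlow_marker")
            scheme.highlow[tissue_scope] = Gate(
                f"{highlow_marker}_high", (highlow_marker,), Interval(highlow_threshold), tissue_scope
            )
        return scheme

    def gate_for(self, role: str, tissue_type: str) -> Gate:
        gates: dict[str, Gate] = getattr(self, role)
        scope = _scope_of(tissue_type)
        gate = gates.get(scope, gates.get("all"))
        if gate is None:
            raise SchemaError(f"no {role} gate for tissue scope {scope!r}")
        return gate

    def has_highlow(self) -> bool:
        return bool(self.highlow)

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def region_dict(region):
            if isinstance(region, Interval):
                hi = None if math.isinf(region.hi) else region.hi
                return {"type": "interval", "lo": region.lo, "hi": hi}
            return {"type": "polygon", "vertices": [list(v) for v in region.vertices]}

        payload = {
            "provenance": self.provenance,
            "gates": [
                {
                    "role": role,
                    "name": g.name,
                    "markers": list(g.markers),
                    "tissue_scope": g.tissue_scope,
                    "region": region_dict(g.region),
                }
                for role in ("master", "split", "highlow")
                for g in getattr(self, role).values()
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GatingScheme":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        roles: dict[str, dict[str, Gate]] = {"master": {}, "split": {}, "highlow": {}}
        for spec in payload["gates"]:
            r = spec["region"]
            if r["type"] == "interval":
                region: Interval | PolygonRegion = Interval(
                    r["lo"], math.inf if r["hi"] is None else r["hi"]
                )
            else:
                region = PolygonRegion(tuple(tuple(v) for v in r["vertices"]))
            gate = Gate(spec["name"], tuple(spec["markers"]), region, spec["tissue_scope"])
            roles[spec["role"]][gate.tissue_scope] = gate
        return cls(
            master=roles["master"],
            split=roles["split"],
            highlow=roles["highlow"],
            provenance=payload.get("provenance", {}),
        )


@dataclass
class PopulationCall:
    """Per-cell population labels plus gate provenance.

    ``labels`` is aligned row-for-row with the gated CellTable and has
    columns: case_id, cell_id, primary_label in {debris, microglia, tam}
    (or {debris, myeloid} after the master gate only), and, when a high/low
    marker was gated, secondary_label in {cd_high, cd_low} (NA for debris)
    and secondary_marker.
    """

    labels: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"case_id", "cell_id", "primary_label"}
        if not required <= set(self.labels.columns):
            raise SchemaError(f"PopulationCall needs columns {sorted(required)}")
        if "secondary_label" in self.labels.columns:
            bad = self.labels.loc[
                (self.labels["primary_label"] == "debris")
                & self.labels["secondary_label"].notna()
            ]
            if len(bad):
                raise IntegrityError("debris cells must not carry a secondary label")

    def counts(self) -> dict[str, int]:
        c = self.labels["primary_label"].value_counts().to_dict()
        out = {k: int(c.get(k, 0)) for k in ("debris", "microglia", "tam", "myeloid")}
        if "secondary_label" in self.labels.columns:
            s = self.labels["secondary_label"].value_counts().to_dict()
            out["cd_high"] = int(s.get("cd_high", 0))
            out["cd_low"] = int(s.get("cd_low", 0))
        return out


def _check_alignment(table: CellTable, calls: PopulationCall) -> None:
    if len(calls.labels) != len(table.df) or not (
        calls.labels["cell_id"].to_numpy() == table.df["cell_id"].to_numpy()
    ).all() or not (
        calls.labels["case_id"].to_numpy() == table.df["case_id"].to_numpy()
    ).all():
        raise IntegrityError("population calls do not cover the table rows")


def apply_master_gate(table: CellTable, scheme: GatingScheme) -> PopulationCall:
    """Debris exclusion on Iba1: cells inside the master region are myeloid."""
    labels = table.df[["case_id", "cell_id"]].copy()
    primary = np.full(len(table.df), "debris", dtype=object)
    for tissue in table.df["tissue_type"].unique():
        gate = scheme.gate_for("master", tissue)
        sel = (table.df["tissue_type"] == tissue).to_numpy()
        sub = CellTable(table.df.loc[sel].reset_index(drop=True), table.area_method)
        primary[np.flatnonzero(sel)[gate.membership(sub)]] = "myeloid"
    labels["primary_label"] = primary
    return PopulationCall(labels, provenance={"master": "applied"})


def classify_microglia_tam(table: CellTable, scheme: GatingScheme) -> PopulationCall:
    """Full primary classification: debris / microglia / tam.

    The master gate is applied first; non-debris cells inside the split
    region become microglia, the rest TAMs (the two regions partition the
    master-gated space by construction).
    """
    master_call = apply_master_gate(table, scheme)
    primary = master_call.labels["primary_label"].to_numpy(dtype=object).copy()
    for tissue in table.df["tissue_type"].unique():
        gate = scheme.gate_for("split", tissue)
        sel = (table.df["tissue_type"] == tissue).to_numpy()
        sub = CellTable(table.df.loc[sel].reset_index(drop=True), table.area_method)
        inside = gate.membership(sub)
        idx = np.flatnonzero(sel)
        nondebris = primary[idx] != "debris"
        primary[idx[nondebris & inside]] = "microglia"
        primary[idx[nondebris & ~inside]] = "tam"
    labels = table.df[["case_id", "cell_id"]].copy()
    labels["primary_label"] = primary
    call = PopulationCall(labels, provenance={"scheme": scheme.provenance})
    if scheme.has_highlow():
        any_scope = next(iter(scheme.highlow.values()))
        marker = any_scope.markers[0]
        if intensity_column(marker) in table.df.columns:
            call = _apply_highlow_from_scheme(table, scheme, call)
    return call


def _apply_highlow_from_scheme(
    table: CellTable, scheme: GatingScheme, call: PopulationCall
) -> PopulationCall:
    labels = call.labels.copy()
    secondary = np.full(len(labels), None, dtype=object)
    marker = None
    for tissue in table.df["tissue_type"].unique():
        gate = scheme.gate_for("highlow", tissue)
        marker = gate.markers[0]
        sel = (table.df["tissue_type"] == tissue).to_numpy()
        sub = CellTable(table.df.loc[sel].reset_index(drop=True), table.area_method)
        inside = gate.membership(sub)
        idx = np.flatnonzero(sel)
        nondebris = labels["primary_label"].to_numpy()[idx] != "debris"
        secondary[idx[nondebris & inside]] = "cd_high"
        secondary[idx[nondebris & ~inside]] = "cd_low"
    labels["secondary_label"] = secondary
    labels["secondary_marker"] = marker
    return PopulationCall(labels, provenance=call.provenance)


@dataclass(frozen=True)
class ControlThreshold:
    """A marker-positivity threshold calibrated from negative-control tissue."""

    value: float
    marker: str
    quantile: float
    n_control_cells: int
    n_control_cases: int


def derive_control_threshold(
    control_tables: Sequence[CellTable], marker: str, quantile: float = 0.99
) -> ControlThreshold:
    """CD14/CD163 positivity threshold from pooled epilepsy (negative-control)
    cells: the stated quantile of their marker means, linear interpolation.
    """
    if not 0.0 < quantile < 1.0:
        raise ValidationError("quantile must be in (0, 1)")
    if marker not in ("CD14", "CD163"):
        raise ValidationError(f"control thresholds are defined for CD14/CD163, got {marker!r}")
    vals = []
    n_cases = 0
    for t in control_tables:
        if len(t.df) and not (t.df["tissue_type"] == "epilepsy").all():
            raise ValidationError("control tables must be epilepsy tissue")
        vals.append(t.intensities(marker).to_numpy())
        n_cases += len(t.case_ids)
    pooled = np.concatenate(vals) if vals else np.array([])
    if pooled.size == 0:
        raise InsufficientDataError("no control cells to derive a threshold from")
    thr = float(np.quantile(pooled, quantile, method="linear"))
    return ControlThreshold(thr, marker, quantile, int(pooled.size), n_cases)


def classify_high_low(
    table: CellTable,
    marker: str,
    threshold: float,
    calls: PopulationCall | None = None,
) -> PopulationCall:
    """Secondary cd_high/cd_low labels: marker mean >= threshold -> cd_high.

    Applied to non-debris cells only; pass the primary-call object so debris
    stays unlabeled.  If ``calls`` is omitted every row is treated as
    non-debris ("myeloid").
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    vals = table.intensities(marker).to_numpy()
    if calls is None:
        labels = table.df[["case_id", "cell_id"]].copy()
        labels["primary_label"] = "myeloid"
    else:
        _check_alignment(table, calls)
        labels = calls.labels.copy()
    nondebris = (labels["primary_label"] != "debris").to_numpy()
    secondary = np.full(len(labels), None, dtype=object)
    secondary[nondebris & (vals >= threshold)] = "cd_high"
    secondary[nondebris & (vals < threshold)] = "cd_low"
    labels["secondary_label"] = secondary
    labels["secondary_marker"] = marker
    prov = dict(calls.provenance) if calls else {}
    prov["highlow_threshold"] = {"marker": marker, "value": float(threshold)}
    return PopulationCall(labels, provenance=prov)


def gate_report(calls: PopulationCall, table: CellTable) -> pd.DataFrame:
    """Per-case population counts: debris, microglia, tam (+ cd_high/cd_low)."""
    _check_alignment(table, calls)
    df = calls.labels
    out = []
    for case_id, sub in df.groupby("case_id", sort=True):
        row = {"case_id": case_id}
        vc = sub["primary_label"].value_counts()
        for k in ("debris", "microglia", "tam"):
            row[k] = int(vc.get(k, 0))
        row["total"] = len(sub)
        if "secondary_label" in df.columns:
            sc = sub["secondary_label"].value_counts()
            row["cd_high"] = int(sc.get("cd_high", 0))
            row["cd_low"] = int(sc.get("cd_low", 0))
        out.append(row)
    return pd.DataFrame(out)


def suggest_split_threshold(values: np.ndarray, seed: int = 0) -> float:
    """Propose a microglia/TAM split threshold from a pooled bimodal sample.

    Fits a two-component 1-D Gaussian mixture and returns the point between
    the component means where the posterior flips.  This is an automation
    convenience — always overridable, and callers should record the value in
    the scheme provenance.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(v) < 10:
        raise InsufficientDataError("need at least 10 cells to suggest a split threshold")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(v)
    m1, m2 = np.sort(gm.means_.ravel())
    grid = np.linspace(m1, m2, 512).reshape(-1, 1)
    post = gm.predict_proba(grid)
    upper = int(np.argmax(gm.means_.ravel()))
    flip = np.argmax(post[:, upper] >= 0.5)
    return float(grid[flip, 0])
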