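"""Reading and writing digitizer-style point series and parameter reports.

Series travel as small delimited text files in the shape produced by
graph-digitizing software: two numeric columns (predictor, rate), an optional
``x,y`` header, comma or tab delimited, with series metadata carried in
``# key: value`` comment lines.  Digitized points carry no uncertainty
column.  A :class:`SeriesRegistry` (a plain-text YAML file) maps series ids
to files plus metadata, so whole study suites can be loaded, refitted and
reported in one pass.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple
import warnings

import numpy as np
import pandas as pd
import yaml

from .core_model import ResponseSeries, ValidationError
from .fitting import FitResult, InsufficientDataError

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "RegistryEntry",
    "SeriesRegistry",
    "load_registry",
    "save_registry",
    "render_parameter_table",
    "parse_estimate_cell",
]

_METADATA_FIELDS = (
    "species",
    "pathway",
    "predictor_kind",
    "predictor_name",
    "x_units",
    "y_units",
    "co2_partial_pressure_Pa",
    "source_ref",
)


def _parse_metadata_line(line: str) -> Optional[Tuple[str, str]]:
    m = re.match(r"#\s*([A-Za-z_][A-Za-z0-9_]*)\s*:\s*(.*)$", line)
    if not m:
        return None
    return m.group(1), m.group(2).strip()


def read_series_csv(path, metadata: Optional[Mapping] = None) -> ResponseSeries:
    """Read a two-column digitizer export into a validated :class:`ResponseSeries`.

    Comma and tab dialects are auto-detected; blank lines and ``#`` comment
    lines are skipped, with ``# key: value`` comments contributing metadata.
    Values in ``metadata`` override anything found in the file.

    Raises
    ------
    ValidationError
        Non-numeric cell (the message names the offending file row) or a
        non-positive rate (the log scale of the nitrogen fit requires y > 0).
    InsufficientDataError
        Fewer than three data rows.
    """
    path = Path(path)
    meta: Dict[str, object] = {}
    rows: List[Tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                kv = _parse_metadata_line(line)
                if kv:
                    meta[kv[0]] = kv[1]
                continue
            cells = [c.strip() for c in re.split(r"[\t,]", line) if c.strip() != ""]
            if len(cells) != 2:
                raise ValidationError(
                    f"{path.name}, row {lineno}: expected two columns, got {len(cells)}"
                )
            if rows == [] and not _is_number(cells[0]):
                # header row such as "x,y"
                continue
            try:
                x_val, y_val = float(cells[0]), float(cells[1])
            except ValueError:
                raise ValidationError(
                    f"{path.name}, row {lineno}: non-numeric cell in {cells!r}"
                ) from None
            rows.append((x_val, y_val))
    if len(rows) < 3:
        raise InsufficientDataError(
            f"{path.name}: at least 3 data rows required, found {len(rows)}"
        )
    if metadata:
        meta.update(metadata)
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    if np.any(y <= 0):
        bad = int(np.argmax(y <= 0))
        raise ValidationError(
            f"{path.name}: y[{bad}] = {y[bad]} is not strictly positive; rates must "
            "be > 0 because the nitrogen response is fitted on the log scale"
        )
    co2 = meta.get("co2_partial_pressure_Pa")
    return ResponseSeries(
        species=str(meta.get("species", "unknown")),
        pathway=str(meta.get("pathway", "C3")),
        predictor_kind=str(meta.get("predictor_kind", "enzyme_activity")),
        predictor_name=str(meta.get("predictor_name", "")),
        x=x,
        y=y,
        x_units=str(meta.get("x_units", "")),
        y_units=str(meta.get("y_units", "µmol CO2 m-2 s-1")),
        co2_partial_pressure_Pa=None if co2 in (None, "", "None") else float(co2),
        source_ref=str(meta.get("source_ref", "")),
    )


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_series_csv(series: ResponseSeries, path) -> None:
    """Write a series as a commented two-column CSV, byte-deterministically.

    Metadata go out as ``# key: value`` lines followed by an ``x,y`` header;
    numbers are written at full precision so a read-back reproduces the
    series exactly.
    """
    path = Path(path)
    lines = []
    for name in _METADATA_FIELDS:
        value = getattr(series, name)
        if value is None or value == "":
            continue
        lines.append(f"# {name}: {value}")
    lines.append("x,y")
    for xi, yi in zip(series.x, series.y):
        lines.append(f"{float(xi)!r},{float(yi)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class RegistryEntry:
    series_id: str
    path: str
    metadata: Dict[str, object] = field(default_factory=dict)
    provenance: str = ""
    missing: bool = False


@dataclass
class SeriesRegistry:
    """Mapping of series ids to files plus metadata and provenance."""

    entries: List[RegistryEntry] = field(default_factory=list)
    base_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        ids = [e.series_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate series ids in registry: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def resolve(self, entry: RegistryEntry) -> Path:
        p = Path(entry.path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p

    def load_series(self, series_id: str) -> ResponseSeries:
        for entry in self.entries:
            if entry.series_id == series_id:
                return read_series_csv(self.resolve(entry), metadata=entry.metadata)
        raise KeyError(f"series id {series_id!r} not in registry")

    def load_all(self) -> Dict[str, ResponseSeries]:
        """Load every non-missing entry; missing files warn and are skipped."""
        out = {}
        for entry in self.entries:
            if entry.missing:
                warnings.warn(f"registry entry {entry.series_id!r} flagged missing; skipped")
                continue
            out[entry.series_id] = read_series_csv(self.resolve(entry), metadata=entry.metadata)
        return out


def load_registry(path) -> SeriesRegistry:
    """Load a YAML registry; entries whose files are absent are flagged, not fatal."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    entries = []
    for item in doc.get("entries", []):
        entry = RegistryEntry(
            series_id=str(item["series_id"]),
            path=str(item["path"]),
            metadata=dict(item.get("metadata", {})),
            provenance=str(item.get("provenance", "")),
        )
        entries.append(entry)
    registry = SeriesRegistry(entries=entries, base_dir=path.parent)
    for entry in registry.entries:
        if not registry.resolve(entry).exists():
            entry.missing = True
            warnings.warn(f"registry entry {entry.series_id!r}: file {entry.path} not found")
    return registry


def save_registry(registry: SeriesRegistry, path) -> None:
    path = Path(path)
    doc = {
        "entries": [
            {
                "series_id": e.series_id,
                "path": e.path,
                "metadata": e.metadata,
                "provenance": e.provenance,
            }
            for e in registry.entries
        ]
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8")


def _cell(estimate: float, se: float) -> str:
    """Render ``estimate (SE)`` with 4 / 3 significant figures."""
    if se is None or not np.isfinite(se):
        return f"{estimate:.4g} (—)"
    return f"{estimate:.4g} ({se:.3g})"


def parse_estimate_cell(cell: str) -> Tuple[float, Optional[float]]:
    """Inverse of the ``estimate (SE)`` cell format, to displayed precision."""
    m = re.match(r"\s*([-+0-9.eE]+)\s*\(([^)]*)\)\s*$", cell)
    if not m:
        raise ValidationError(f"cannot parse estimate cell {cell!r}")
    est = float(m.group(1))
    se_text = m.group(2).strip()
    se = None if se_text in ("—", "", "-") else float(se_text)
    return est, se


def render_parameter_table(results: Mapping[str, FitResult], layout: str) -> pd.DataFrame:
    """Render fitted parameters in one of the two report layouts.

    ``layout='enzyme'``: one row per labelled exponential fit with
    ``alpha (SE)``, ``b (SE)`` and raw-scale R² columns — the shape used for
    enzyme-activity relationships.  ``layout='nitrogen'``: one column per
    labelled nitrogen-response fit with ``ln_P_max``, ``Kp`` and ln-scale R²
    rows.  Mixing model kinds within one layout is a validation error; an
    empty input renders an empty table with the layout's header.
    """
    if layout not in ("enzyme", "nitrogen"):
        raise ValidationError(f"layout must be 'enzyme' or 'nitrogen', got {layout!r}")
    if layout == "enzyme":
        rows = []
        for label, fit in results.items():
            if fit.model_kind != "exponential":
                raise ValidationError(
                    f"enzyme layout accepts exponential fits only, got {fit.model_kind!r} "
                    f"for {label!r}"
                )
            se = dict(zip(fit.param_names, fit.se))
            rows.append(
                {
                    "predictor": label,
                    "alpha (SE)": _cell(fit.params.alpha, se["alpha"]),
                    "b (SE)": _cell(fit.params.b, se["b"]),
                    "R2": round(fit.r_squared, 2),
                }
            )
        return pd.DataFrame(rows, columns=["predictor", "alpha (SE)", "b (SE)", "R2"])
    columns = {}
    for label, fit in results.items():
        if not fit.model_kind.startswith("resource_response"):
            raise ValidationError(
                f"nitrogen layout accepts resource-response fits only, got "
                f"{fit.model_kind!r} for {label!r}"
            )
        columns[label] = {
            "ln_P_max": f"{fit.params.ln_P_max:.4g}",
            "Kp": f"{fit.params.Kp:.4g}",
            "R2": f"{fit.r_squared:.2f}",
        }
    frame = pd.DataFrame(columns)
    if frame.empty:
        frame = pd.DataFrame(index=pd.Index(["ln_P_max", "Kp", "R2"], name="parameter"))
    else:
        frame.index.name = "parameter"
    return frame
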