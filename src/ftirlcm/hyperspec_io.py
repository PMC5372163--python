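"""Readers and writers for all pipeline artifacts.

Hyperspectral absorbance cubes travel as a single ``.npz`` binary (cube +
optional QC mask) with a JSON metadata sidecar (``<path>.json``) holding the
wavenumber axis, pixel geometry and stage origin.  Label maps are paletted
PNGs with a JSON legend sidecar.  Dissection shapes are exported as a neutral
XML or CSV dialect; reference points and protein tables as CSV.

All coordinates are micrometres, all wavenumbers cm^-1.  Pixel indices are
0-based (row, col); the stage position of pixel (r, c) is
``(origin_x + (c + 0.5) * pixel_w, origin_y + (r + 0.5) * pixel_h)`` with
stage y increasing downward.  Band storage order is descending wavenumber;
the axis carries the truth and every operation indexes by wavenumber, never
by raw band position.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, StructuralError, ValidationError

__all__ = [
    "WavenumberAxis",
    "SpectralImage",
    "LabelMap",
    "ReferencePointSet",
    "ProteinAbundanceTable",
    "pixel_centers_um",
    "read_cube",
    "write_cube",
    "read_label_map",
    "write_label_map",
    "export_lcm_shapes",
    "read_lcm_shapes",
    "read_reference_points",
    "write_reference_points",
    "read_protein_table",
]

ACQUISITION_RANGE = (950.0, 2700.0)


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotonic wavenumber grid (cm^-1), uniform spacing."""

    values: np.ndarray
    nominal_resolution: float = 4.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise StructuralError("wavenumber axis must be a 1-d array of >=2 points")
        steps = np.diff(values)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise StructuralError("wavenumber axis must be strictly monotonic")
        mean_step = steps.mean()
        if np.max(np.abs(steps - mean_step)) > 1e-6 * abs(mean_step):
            raise StructuralError("wavenumber axis spacing must be uniform")

    def __len__(self) -> int:
        return self.values.size

    @property
    def descending(self) -> bool:
        return self.values[0] > self.values[-1]

    @property
    def step(self) -> float:
        """Absolute grid spacing in cm^-1."""
        return float(abs(self.values[1] - self.values[0]))

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of axis points inside the closed interval [lo, hi]."""
        if lo > hi:
            lo, hi = hi, lo
        idx = np.nonzero((self.values >= lo) & (self.values <= hi))[0]
        if idx.size == 0:
            from .errors import WindowError

            raise WindowError(
                f"window [{lo}, {hi}] cm^-1 contains no axis points "
                f"(axis spans [{self.values.min()}, {self.values.max()}])"
            )
        return idx

    @classmethod
    def acquisition_default(cls) -> "WavenumberAxis":
        """Descending 2700 -> 952 cm^-1 grid at 4 cm^-1 (438 bands)."""
        n = int(np.floor((ACQUISITION_RANGE[1] - ACQUISITION_RANGE[0]) / 4.0)) + 1
        return cls(ACQUISITION_RANGE[1] - 4.0 * np.arange(n), nominal_resolution=4.0)


@dataclass
class SpectralImage:
    """Absorbance cube [rows x cols x bands] with geometry and QC mask."""

    cube: np.ndarray
    axis: WavenumberAxis
    pixel_size: tuple[float, float] = (5.5, 5.5)
    stage_origin: tuple[float, float] = (0.0, 0.0)
    qc_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3:
            raise StructuralError("cube must be rows x cols x bands")
        if self.cube.shape[2] != len(self.axis):
            raise StructuralError(
                f"cube has {self.cube.shape[2]} bands but axis has {len(self.axis)} points"
            )
        if self.pixel_size[0] <= 0 or self.pixel_size[1] <= 0:
            raise ValidationError("pixel_size components must be positive")
        if self.qc_mask is None:
            self.qc_mask = np.ones(self.cube.shape[:2], dtype=bool)
        else:
            self.qc_mask = np.asarray(self.qc_mask, dtype=bool)
            if self.qc_mask.shape != self.cube.shape[:2]:
                raise StructuralError("qc_mask shape must match cube rows x cols")
        if not np.all(np.isfinite(self.cube[self.qc_mask])):
            raise ValidationError("absorbance must be finite wherever qc_mask is true")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]


def pixel_centers_um(
    rows: np.ndarray,
    cols: np.ndarray,
    pixel_size: tuple[float, float],
    stage_origin: tuple[float, float],
) -> np.ndarray:
    """Stage coordinates (x, y) um of pixel centers for (row, col) indices."""
    x = stage_origin[0] + (np.asarray(cols, float) + 0.5) * pixel_size[0]
    y = stage_origin[1] + (np.asarray(rows, float) + 0.5) * pixel_size[1]
    return np.column_stack([x, y])


@dataclass
class LabelMap:
    """Per-pixel integer class indices; 0 means unclassified/rejected."""

    labels: np.ndarray
    legend: dict[int, tuple[str, str]]  # label -> (class name, display color)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise StructuralError("label map must be 2-d")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label map must hold integers")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} missing from legend")

    def class_name(self, label: int) -> str:
        return self.legend[label][0]


@dataclass
class ReferencePointSet:
    """Paired fiducial coordinates in two stage frames (um)."""

    pairs: list[tuple[tuple[float, float], tuple[float, float]]]
    source_frame: str = "ftir"
    destination_frame: str = "lcm"

    def __post_init__(self) -> None:
        self.pairs = [
            (tuple(map(float, s)), tuple(map(float, d))) for s, d in self.pairs
        ]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def source(self) -> np.ndarray:
        return np.array([s for s, _ in self.pairs], dtype=float)

    @property
    def destination(self) -> np.ndarray:
        return np.array([d for _, d in self.pairs], dtype=float)

    def require_estimable(self, tol: float = 1e-9) -> None:
        """Raise unless >=3 pairs exist and the sources are non-collinear."""
        from .errors import ConditioningError

        if len(self) < 3:
            raise ConditioningError("transform estimation needs >=3 reference pairs")
        src = self.source
        # max triangle area over all point triples
        best = 0.0
        for i in range(len(src)):
            for j in range(i + 1, len(src)):
                for k in range(j + 1, len(src)):
                    a, b, c = src[i], src[j], src[k]
                    area = 0.5 * abs(
                        (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
                    )
                    best = max(best, area)
        if best <= tol:
            raise ConditioningError("reference points are collinear or duplicated")


# ---------------------------------------------------------------------------
# cube container


def write_cube(image: SpectralImage, path: str | Path) -> Path:
    """Write a cube as ``<path>`` (.npz) plus a ``<path>.json`` sidecar."""
    path = Path(path)
    np.savez(path, cube=image.cube, qc_mask=image.qc_mask)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = {
        "axis_values_cm1": image.axis.values.tolist(),
        "nominal_resolution_cm1": image.axis.nominal_resolution,
        "pixel_size_um": list(image.pixel_size),
        "stage_origin_um": list(image.stage_origin),
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta))
    return path


def read_cube(path: str | Path) -> SpectralImage:
    """Read a cube written by :func:`write_cube`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cube file not found: {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("axis_values_cm1", "pixel_size_um", "stage_origin_um"):
        if key not in meta:
            raise FormatError(f"metadata sidecar missing field '{key}'")
    with np.load(path) as archive:
        cube = archive["cube"]
        qc_mask = archive["qc_mask"] if "qc_mask" in archive else None
    axis = WavenumberAxis(
        np.asarray(meta["axis_values_cm1"], dtype=float),
        nominal_resolution=float(meta.get("nominal_resolution_cm1", 4.0)),
    )
    if cube.ndim != 3 or cube.shape[2] != len(axis):
        raise StructuralError(
            f"cube has {cube.shape[2] if cube.ndim == 3 else '?'} bands "
            f"but axis declares {len(axis)}"
        )
    return SpectralImage(
        cube=cube,
        axis=axis,
        pixel_size=tuple(meta["pixel_size_um"]),
        stage_origin=tuple(meta["stage_origin_um"]),
        qc_mask=qc_mask,
    )


# ---------------------------------------------------------------------------
# label maps


def write_label_map(label_map: LabelMap, path: str | Path) -> Path:
    """Write labels as a paletted PNG plus a JSON legend sidecar."""
    path = Path(path)
    labels = label_map.labels
    if labels.max(initial=0) > 255:
        raise ValidationError("paletted PNG supports at most 255 classes")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = [0, 0, 0] * 256
    for label, (_, color) in label_map.legend.items():
        r, g, b = _hex_to_rgb(color)
        palette[3 * label : 3 * label + 3] = [r, g, b]
    img.putpalette(palette)
    img.save(path)
    legend = {
        str(label): {"name": name, "color": color}
        for label, (name, color) in label_map.legend.items()
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(legend))
    return path


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"label map not found: {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"legend sidecar not found: {sidecar}")
    labels = np.asarray(Image.open(path), dtype=np.int32)
    legend_raw = json.loads(sidecar.read_text())
    legend = {
        int(k): (v["name"], v["color"]) for k, v in legend_raw.items()
    }
    return LabelMap(labels=labels, legend=legend)


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return tuple(int(color[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# LCM shape export


def _validate_polygon(vertices: np.ndarray, index: int) -> np.ndarray:
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] < 3:
        raise ValidationError(f"shape {index}: polygon needs >=3 (x, y) vertices")
    if not np.all(np.isfinite(vertices)):
        raise ValidationError(f"shape {index}: non-finite vertex coordinates")
    if _self_intersects(vertices):
        raise ValidationError(f"shape {index}: polygon is self-intersecting")
    return vertices


def _self_intersects(poly: np.ndarray) -> bool:
    """Segment-pair crossing test for small dissection polygons."""
    n = poly.shape[0]
    segs = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent segments share an endpoint
            if _segments_cross(*segs[i], *segs[j]):
                return True
    return False


def _segments_cross(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def export_lcm_shapes(
    shapes: list[np.ndarray], path: str | Path, dialect: str = "xml"
) -> Path:
    """Export dissection polygons (destination-frame um) as XML or CSV.

    Coordinates are written with 0.01 um precision.  Shape order and vertex
    order are preserved.
    """
    path = Path(path)
    validated = [_validate_polygon(s, i) for i, s in enumerate(shapes)]
    if dialect == "xml":
        root = ET.Element("lcm_shapes", attrib={"units": "um", "count": str(len(validated))})
        for i, poly in enumerate(validated):
            shape = ET.SubElement(root, "shape", attrib={"id": str(i)})
            for x, y in poly:
                ET.SubElement(shape, "point", attrib={"x": f"{x:.2f}", "y": f"{y:.2f}"})
        ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    elif dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["shape_id", "vertex_index", "x_um", "y_um"])
            for i, poly in enumerate(validated):
                for j, (x, y) in enumerate(poly):
                    writer.writerow([i, j, f"{x:.2f}", f"{y:.2f}"])
    else:
        raise ValidationError(f"unknown shape dialect '{dialect}' (use 'xml' or 'csv')")
    return path


def read_lcm_shapes(path: str | Path, dialect: str = "xml") -> list[np.ndarray]:
    path = Path(path)
    if dialect == "xml":
        root = ET.parse(path).getroot()
        shapes = []
        for shape in root.iter("shape"):
            pts = [(float(p.get("x")), float(p.get("y"))) for p in shape.iter("point")]
            shapes.append(np.array(pts, dtype=float))
        return shapes
    if dialect == "csv":
        df = pd.read_csv(path)
        return [
            grp.sort_values("vertex_index")[["x_um", "y_um"]].to_numpy(dtype=float)
            for _, grp in df.groupby("shape_id", sort=True)
        ]
    raise ValidationError(f"unknown shape dialect '{dialect}'")


# ---------------------------------------------------------------------------
# reference points


def write_reference_points(points: ReferencePointSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["src_x_um", "src_y_um", "dst_x_um", "dst_y_um"]
        )
        for (sx, sy), (dx, dy) in points.pairs:
            writer.writerow([repr(sx), repr(sy), repr(dx), repr(dy)])
    return path


def read_reference_points(
    path: str | Path, source_frame: str = "ftir", destination_frame: str = "lcm"
) -> ReferencePointSet:
    df = pd.read_csv(path)
    pairs = [
        ((row.src_x_um, row.src_y_um), (row.dst_x_um, row.dst_y_um))
        for row in df.itertuples()
    ]
    return ReferencePointSet(pairs, source_frame, destination_frame)


# ---------------------------------------------------------------------------
# protein abundance tables


@dataclass
class ProteinAbundanceTable:
    """Normalized protein abundances with group / replicate design.

    ``abundances`` is proteins x runs; ``design`` maps each run column to a
    biological sample, a group (e.g. epithelioid / sarcomatoid) and a
    technical-replicate index.
    """

    proteins: pd.DataFrame  # columns: accession, gene, unique_peptides
    abundances: pd.DataFrame  # index aligned with proteins; columns = run ids
    design: pd.DataFrame  # columns: run, sample, group, replicate

    def __post_init__(self) -> None:
        required = {"accession", "gene", "unique_peptides"}
        if not required.issubset(self.proteins.columns):
            raise ValidationError(f"protein sheet must have columns {sorted(required)}")
        if self.proteins["accession"].duplicated().any():
            dups = self.proteins.loc[
                self.proteins["accession"].duplicated(), "accession"
            ].tolist()
            raise ValidationError(f"duplicate accession(s): {dups}")
        design_cols = {"run", "sample", "group", "replicate"}
        if not design_cols.issubset(self.design.columns):
            raise ValidationError(f"design must have columns {sorted(design_cols)}")
        runs = list(self.abundances.columns)
        mapped = list(self.design["run"])
        unmapped = set(runs) - set(mapped)
        if unmapped:
            raise ValidationError(f"abundance column(s) absent from design: {sorted(unmapped)}")
        if self.design["run"].duplicated().any():
            raise ValidationError("design maps a run column more than once")
        extra = set(mapped) - set(runs)
        if extra:
            raise ValidationError(f"design references missing run column(s): {sorted(extra)}")
        values = self.abundances.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValidationError("abundances must be nonnegative")

    @property
    def groups(self) -> dict[str, list[str]]:
        """Group name -> sorted list of biological samples."""
        out: dict[str, list[str]] = {}
        for group, sub in self.design.groupby("group"):
            out[str(group)] = sorted(sub["sample"].unique().tolist())
        return out

    def runs_for_sample(self, sample: str) -> list[str]:
        return self.design.loc[self.design["sample"] == sample, "run"].tolist()


def read_protein_table(path: str | Path, design_path: str | Path) -> ProteinAbundanceTable:
    """Read a quantification export (CSV/TSV) plus its run-design mapping.

    The main table must carry ``accession``, ``gene`` and ``unique_peptides``
    columns; every remaining column is an abundance run that the design file
    must assign to exactly one (sample, group, replicate).
    """
    path, design_path = Path(path), Path(design_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("accession", "gene", "unique_peptides"):
        if col not in df.columns:
            raise FormatError(f"protein table missing column '{col}'")
    run_cols = [c for c in df.columns if c not in ("accession", "gene", "unique_peptides")]
    if not run_cols:
        raise FormatError("protein table has no abundance columns")
    design = pd.read_csv(design_path)
    return ProteinAbundanceTable(
        proteins=df[["accession", "gene", "unique_peptides"]].copy(),
        abundances=df[run_cols].astype(float),
        design=design,
    )
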