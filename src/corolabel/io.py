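"""Readers and writers binding the pipeline together.

Formats: legacy-ASCII VTK polydata for centerlines (one polyline cell per
branch, optional integer cell-data labels with a codebook written
alongside), NIfTI / MetaImage for binary masks, XYZ CSV for chamber point
clouds, JSON for segment label files, YAML for pipeline configuration.

All files record the coordinate frame explicitly (``frame: LAI`` — x
toward patient left, y anterior, z inferior); silent frame conversion
would corrupt every distance the labeler relies on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .geometry import Centerline, PointCloud
from .labeler import SEGMENT_LABELS, LabeledFragment, LabeledTree, LabelerConfig
from .skeleton import BinaryVolume

__all__ = [
    "read_centerlines",
    "write_centerlines",
    "read_mask",
    "write_mask",
    "read_cloud",
    "write_cloud",
    "read_labels",
    "write_labels",
    "PipelineConfig",
]

FORMAT_VERSION = "1"
FRAME = "LAI"  # x: right->left, y: back->front (anterior), z: top->bottom (inferior)

_LABEL_CODES = {lab: i + 1 for i, lab in enumerate(SEGMENT_LABELS)}


# ---------------------------------------------------------------------------
# VTK legacy ASCII polydata (the subset the pipeline uses)
# ---------------------------------------------------------------------------

def write_centerlines(path, centerlines, labels=None):
    """Write polylines as legacy-ASCII VTK polydata.

    One LINES cell per centerline; if ``labels`` (one string per line) is
    given, an integer cell-data array ``segment_label`` is written and the
    codebook is stored in the header comment.
    """
    centerlines = list(centerlines)
    n_pts = sum(len(c) for c in centerlines)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        codebook = "" if labels is None else " codebook=" + ",".join(
            f"{v}:{k}" for k, v in _LABEL_CODES.items()
        )
        f.write(f"corolabel centerlines v{FORMAT_VERSION} frame={FRAME}{codebook}\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {n_pts} float\n")
        for c in centerlines:
            for p in c.points:
                f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        size = sum(len(c) + 1 for c in centerlines)
        f.write(f"LINES {len(centerlines)} {size}\n")
        offset = 0
        for c in centerlines:
            ids = " ".join(str(offset + i) for i in range(len(c)))
            f.write(f"{len(c)} {ids}\n")
            offset += len(c)
        if labels is not None:
            f.write(f"CELL_DATA {len(centerlines)}\n")
            f.write("SCALARS segment_label int 1\nLOOKUP_TABLE default\n")
            for lab in labels:
                f.write(f"{_LABEL_CODES.get(lab, 0)}\n")


def read_centerlines(path):
    """Read polyline cells from a legacy-ASCII VTK polydata file.

    Returns ``(centerlines, labels_or_None)``. Point order inside each
    polyline is preserved; coordinates are taken as mm in the package
    frame.
    """
    with open(path) as f:
        lines = f.read().splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise ValueError(f"{path}: not a legacy VTK file (bad magic line)")
    tokens: list[str] = []
    header_cursor = {"points": None, "lines": None, "cell_scalars": None}
    i = 0
    pts = None
    polylines = []
    cell_labels = None
    n_lines_expected = 0
    while i < len(lines):
        line = lines[i].strip()
        up = line.upper()
        if up.startswith("POINTS"):
            try:
                n = int(line.split()[1])
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{i + 1}: malformed POINTS header {line!r}")
            vals = []
            while len(vals) < 3 * n:
                i += 1
                if i >= len(lines):
                    raise ValueError(f"{path}:{i}: truncated POINTS block")
                vals.extend(float(t) for t in lines[i].split())
            pts = np.array(vals).reshape(n, 3)
        elif up.startswith("LINES"):
            parts = line.split()
            n_lines_expected = int(parts[1])
            vals = []
            # legacy form: each cell is "n id0 id1 ... id{n-1}"
            total = int(parts[2])
            while len(vals) < total:
                i += 1
                if i >= len(lines):
                    raise ValueError(f"{path}:{i}: truncated LINES block")
                vals.extend(int(t) for t in lines[i].split())
            j = 0
            for _ in range(n_lines_expected):
                n = vals[j]
                polylines.append(vals[j + 1 : j + 1 + n])
                j += n + 1
        elif up.startswith("SCALARS") and "segment_label" in line:
            i += 1  # LOOKUP_TABLE line
            vals = []
            while len(vals) < n_lines_expected and i + 1 < len(lines):
                i += 1
                stripped = lines[i].strip()
                if not stripped:
                    continue
                vals.extend(int(t) for t in stripped.split())
            inv = {v: k for k, v in _LABEL_CODES.items()}
            cell_labels = [inv.get(v) for v in vals]
        i += 1
    if pts is None or not polylines:
        raise ValueError(f"{path}: no polyline cells found")
    centerlines = [Centerline(pts[ids]) for ids in polylines]
    return centerlines, cell_labels


# ---------------------------------------------------------------------------
# masks and clouds
# ---------------------------------------------------------------------------

def write_mask(path, vol: BinaryVolume):
    """Write a binary volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.uint8), affine), path)
    elif path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.voxels.astype(np.uint8).transpose(2, 1, 0))
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unsupported mask format: {path}")


def read_mask(path) -> BinaryVolume:
    """Read a binary mask; voxel order (i,j,k) maps to world (x,y,z)."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        origin = aff[:3, 3]
        return BinaryVolume(np.asarray(img.dataobj) > 0, spacing, origin)
    if path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return BinaryVolume(arr > 0, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
    raise ValueError(f"unsupported mask format: {path}")


def write_cloud(path, cloud: PointCloud):
    pd.DataFrame(cloud.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_cloud(path, role: str = "other") -> PointCloud:
    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return PointCloud(df[["x", "y", "z"]].to_numpy(float), role=role)


# ---------------------------------------------------------------------------
# label files (JSON)
# ---------------------------------------------------------------------------

def write_labels(tree: LabeledTree, path, case_id: str = ""):
    doc = {
        "format_version": FORMAT_VERSION,
        "frame": FRAME,
        "case_id": case_id,
        "fragments": [
            {
                "label": f.label,
                "parent": f.parent,
                "start_mm": round(float(f.start_mm), 6),
                "end_mm": round(float(f.end_mm), 6),
                "points": np.round(f.points, 6).tolist(),
            }
            for f in tree.fragments
        ],
        "provenance": tree.provenance,
        "warnings": tree.warnings,
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)


def read_labels(path) -> LabeledTree:
    with open(path) as f:
        doc = json.load(f)
    for key in ("fragments", "frame"):
        if key not in doc:
            raise ValueError(f"{path}: label file missing field {key!r}")
    frags = []
    for k, fr in enumerate(doc["fragments"]):
        for key in ("label", "parent", "start_mm", "end_mm", "points"):
            if key not in fr:
                raise ValueError(f"{path}: fragment {k} missing field {key!r}")
        if fr["label"] not in SEGMENT_LABELS:
            raise ValueError(f"{path}: fragment {k} has out-of-vocabulary label {fr['label']!r}")
        frags.append(
            LabeledFragment(
                fr["label"], fr["parent"], np.asarray(fr["points"], float),
                float(fr["start_mm"]), float(fr["end_mm"]),
            )
        )
    return LabeledTree(frags, doc.get("provenance", {}), doc.get("warnings", []))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Serializable configuration for the end-to-end pipeline."""

    labeler: LabelerConfig = field(default_factory=LabelerConfig)
    spur_min_mm: float = 3.0
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path):
        doc = {
            "labeler": asdict(self.labeler),
            "spur_min_mm": self.spur_min_mm,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        with open(path, "w") as f:
            yaml.safe_dump(doc, f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        lab = doc.get("labeler", {})
        known = {f.name for f in fields(LabelerConfig)}
        unknown = set(lab) - known
        if unknown:
            raise ValueError(f"{path}: unknown labeler options {sorted(unknown)}")
        if "subdivision_fractions" in lab:
            lab["subdivision_fractions"] = tuple(lab["subdivision_fractions"])
        return cls(
            labeler=LabelerConfig(**lab),
            spur_min_mm=float(doc.get("spur_min_mm", 3.0)),
            seed=int(doc.get("seed", 0)),
            log_level=str(doc.get("log_level", "INFO")),
        )

    def __eq__(self, other):
        if not isinstance(other, PipelineConfig):
            return NotImplemented
        return (
            asdict(self.labeler) == asdict(other.labeler)
            and self.spur_min_mm == other.spur_min_mm
            and self.seed == other.seed
            and self.log_level == other.log_level
        )
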