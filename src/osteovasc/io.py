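"""Volume and configuration I/O.

Supported volume formats: TIFF stacks (ImageJ-flavored metadata), MetaImage
(``.mha``/``.mhd``), NIfTI (``.nii``/``.nii.gz``) and raw binary with a JSON
sidecar.  Axis order on disk and in memory is slices-first ``(z, y, x)``.
Voxel size is stored in the image header in µm and read back from it; when a
header carries no voxel size an explicit override is required.

Label volumes must use the four-class vocabulary {0 background, 1 bone,
2 vessel, 3 metastasis}; unknown ids are rejected at load time.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile
import yaml

from .phantom import (
    CohortSpec,
    GroupEffect,
    MetastasisSpec,
    PhantomSpec,
    RenderSpec,
    ShellSpec,
    TrabeculaeSpec,
    VesselSpec,
)
from .volume import IntensityVolume, LabelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_ground_truth",
    "load_config",
    "phantom_spec_from_dict",
    "cohort_spec_from_dict",
]

_TIFF = (".tif", ".tiff")
_MHA = (".mha", ".mhd")
_NII = (".nii", ".nii.gz")
_RAW = (".raw",)


def _format_of(path: Path, hint: str | None) -> str:
    if hint:
        return hint
    name = path.name.lower()
    if name.endswith(_NII):
        return "nifti"
    suffix = path.suffix.lower()
    if suffix in _TIFF:
        return "tiff"
    if suffix in _MHA:
        return "metaimage"
    if suffix in _RAW:
        return "raw"
    raise ValueError(f"cannot infer a volume format from {path.name!r}")


# ---------------------------------------------------------------------------
# writers


def write_volume(vol: LabelVolume | IntensityVolume, path, format: str | None = None) -> Path:
    """Write a volume with its voxel size (µm) in the header."""
    path = Path(path)
    fmt = _format_of(path, format)
    data = vol.data
    vs = vol.voxel_size_um  # (z, y, x)
    if fmt == "tiff":
        # ImageJ convention: XY resolution in pixels per unit, z as 'spacing'
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / vs[2], 1.0 / vs[1]),
            metadata={"spacing": vs[0], "unit": "um", "axes": "ZYX"},
        )
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((vs[2], vs[1], vs[0]))  # sitk spacing is (x, y, z)
        sitk.WriteImage(img, str(path))
    elif fmt == "nifti":
        # nibabel's array axes map to (x, y, z); store transposed so that the
        # on-disk fastest axis is x, and mark units as micron
        affine = np.diag([vs[2], vs[1], vs[0], 1.0])
        ni = nib.Nifti1Image(np.asarray(data).transpose(2, 1, 0), affine)
        ni.header.set_xyzt_units(xyz="micron")
        nib.save(ni, path)
    elif fmt == "raw":
        data = np.ascontiguousarray(data)
        data.tofile(path)
        sidecar = {
            "shape": list(data.shape),
            "dtype": data.dtype.str,
            "voxel_size_um": list(vs),
            "axes": "ZYX",
            "kind": "labels" if isinstance(vol, LabelVolume) else "intensity",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_ground_truth(truth, path) -> Path:
    """Serialize a PhantomGroundTruth (minus the dense branch-id map) as JSON."""
    path = Path(path)
    payload = {
        "class_counts": {str(k): v for k, v in truth.class_counts.items()},
        "analytic_volumes_um3": truth.analytic_volumes_um3,
        "branch_radii_um": truth.branch_radii_um,
        "segments": truth.segments,
        "lesions": truth.lesions,
        "effect": truth.effect,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# readers


def _read_arrays(path: Path, fmt: str, voxel_size_um):
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            vs = None
            meta = tf.imagej_metadata or {}
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if "spacing" in meta and xres and yres:
                dz = float(meta["spacing"])
                dx = xres.value[1] / xres.value[0]
                dy = yres.value[1] / yres.value[0]
                vs = (dz, dy, dx)
    elif fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        sx, sy, sz = img.GetSpacing()
        vs = (sz, sy, sx)
    elif fmt == "nifti":
        ni = nib.load(path)
        data = np.asarray(ni.dataobj).transpose(2, 1, 0)
        zx, zy, zz = ni.header.get_zooms()[:3]
        vs = (float(zz), float(zy), float(zx))
    elif fmt == "raw":
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"raw volume {path} has no JSON sidecar {sidecar_path.name}")
        sidecar = json.loads(sidecar_path.read_text())
        data = np.fromfile(path, dtype=np.dtype(sidecar["dtype"])).reshape(sidecar["shape"])
        vs = tuple(sidecar["voxel_size_um"]) if "voxel_size_um" in sidecar else None
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if voxel_size_um is not None:
        vs = tuple(float(v) for v in np.broadcast_to(voxel_size_um, (3,)))
    if vs is None:
        raise ValueError(
            f"{path.name}: no voxel size in the header and none supplied; pass voxel_size_um"
        )
    return data, vs


def read_volume(
    path, kind: str = "labels", voxel_size_um=None, format: str | None = None
) -> LabelVolume | IntensityVolume:
    """Read a volume as a :class:`LabelVolume` (``kind="labels"``) or
    :class:`IntensityVolume` (``kind="intensity"``).

    The voxel size comes from the file header; ``voxel_size_um`` overrides it
    and is required if the header has none.  Label volumes must be
    integer-typed and within the four-class vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_of(path, format)
    data, vs = _read_arrays(path, fmt, voxel_size_um)
    if kind == "labels":
        if not np.issubdtype(data.dtype, np.integer):
            if np.allclose(data, np.round(data)):
                data = np.round(data).astype(np.uint8)
            else:
                raise TypeError(f"{path.name}: non-integer data cannot be a label volume")
        return LabelVolume(data, vs)
    if kind == "intensity":
        return IntensityVolume(np.asarray(data, float), vs)
    raise ValueError(f"kind must be 'labels' or 'intensity', got {kind!r}")


# ---------------------------------------------------------------------------
# configuration


def _build(cls, d: dict, name: str):
    try:
        return cls(**d)
    except TypeError as exc:
        raise ValueError(f"invalid {name} config: {exc}") from None


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    """Build a PhantomSpec from a (YAML-friendly) nested dict."""
    d = dict(d)
    parts = {
        "shell": ShellSpec,
        "trabeculae": TrabeculaeSpec,
        "vessels": VesselSpec,
        "metastases": MetastasisSpec,
        "render": RenderSpec,
    }
    kwargs: dict = {}
    for key, cls in parts.items():
        if key in d:
            sub = dict(d.pop(key))
            for field_name in ("radius_range_um", "semi_axis_range_um"):
                if field_name in sub:
                    sub[field_name] = tuple(sub[field_name])
            kwargs[key] = _build(cls, sub, key)
    for key in ("grid_shape", "voxel_size_um"):
        if key in d:
            kwargs[key] = tuple(np.broadcast_to(d.pop(key), (3,)).tolist())
    if "seed" in d:
        kwargs["seed"] = int(d.pop("seed"))
    if d:
        raise ValueError(f"unknown phantom config keys: {sorted(d)}")
    return PhantomSpec(**kwargs)


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a nested dict (keys: groups, base, time_point, seed)."""
    d = dict(d)
    groups = [_build(GroupEffect, dict(g), "group") for g in d.pop("groups")]
    base = phantom_spec_from_dict(d.pop("base", {}))
    spec = CohortSpec(
        groups=groups,
        base=base,
        time_point=str(d.pop("time_point", "T2")),
        seed=int(d.pop("seed", 0)),
    )
    if d:
        raise ValueError(f"unknown cohort config keys: {sorted(d)}")
    spec.validate()
    return spec


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    return cfg
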