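"""Reading and writing vertex maps: FreeSurfer curv, GIFTI, delimited text.

All formats carry one value per mesh vertex.  Vertex indexing is 0-based,
including in the on-disk delimited text.  Masked (invalid) vertices are stored
as NaN; for formats that cannot carry a name (curv, TSV) a small JSON sidecar
``<path>.json`` records the map name and the masked vertex indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .surface import MeshMismatchError, Parcellation, SphereMesh, VertexMap

__all__ = ["read_map", "write_map", "MapIOError", "write_mesh_gifti", "write_annot", "read_annot"]


class MapIOError(ValueError):
    """A map file could not be parsed; the message names the offending record."""


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path: Path, vmap: VertexMap) -> None:
    meta = {
        "name": vmap.name,
        "n_vertices": int(vmap.n_vertices),
        "masked_indices": np.flatnonzero(~vmap.mask).tolist(),
        "mesh_id": vmap.mesh_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def _read_sidecar(path: Path, n_vertices: int) -> tuple[str, np.ndarray, str]:
    sc = _sidecar_path(path)
    name, mesh_id = "", ""
    mask = np.ones(n_vertices, dtype=bool)
    if sc.exists():
        meta = json.loads(sc.read_text())
        name = meta.get("name", "")
        mesh_id = meta.get("mesh_id", "")
        idx = np.asarray(meta.get("masked_indices", []), dtype=int)
        if len(idx):
            mask[idx] = False
    return name, mask, mesh_id


def write_map(path: str | Path, vmap: VertexMap) -> None:
    """Write a vertex map; format chosen from the suffix.

    ``.curv`` FreeSurfer curv (new binary format), ``.gii`` GIFTI functional
    data, ``.tsv``/``.txt`` two-column delimited text (vertex index, value).
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix == ".curv":
        nib.freesurfer.io.write_morph_data(str(path), vmap.values)
        _write_sidecar(path, vmap)
    elif suffixes.endswith(".gii"):
        darr = nib.gifti.GiftiDataArray(
            vmap.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
        )
        img = nib.gifti.GiftiImage(darrays=[darr])
        img.meta["cogmorph_name"] = vmap.name
        img.meta["cogmorph_mesh_id"] = vmap.mesh_id
        nib.save(img, str(path))
    elif path.suffix in (".tsv", ".txt"):
        with open(path, "w") as fh:
            fh.write("vertex\tvalue\n")
            for i, v in enumerate(vmap.values):
                fh.write(f"{i}\t{float(v)!r}\n" if np.isfinite(v) else f"{i}\tnan\n")
        _write_sidecar(path, vmap)
    else:
        raise ValueError(f"unsupported map format: {path.name}")


def read_map(path: str | Path, mesh: SphereMesh | None = None) -> VertexMap:
    """Read a vertex map written by :func:`write_map`.

    If ``mesh`` is given, the vertex count is validated against it and the
    map's mask is intersected with the cortex mask.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix == ".curv":
        try:
            values = np.asarray(nib.freesurfer.io.read_morph_data(str(path)), dtype=float)
        except Exception as exc:  # nibabel raises various types on bad magic
            raise MapIOError(f"{path.name}: not a readable FreeSurfer curv file ({exc})") from exc
        name, mask, mesh_id = _read_sidecar(path, len(values))
    elif suffixes.endswith(".gii"):
        img = nib.load(str(path))
        if not img.darrays:
            raise MapIOError(f"{path.name}: GIFTI file contains no data arrays")
        values = np.asarray(img.darrays[0].data, dtype=float)
        name = img.meta.get("cogmorph_name", "") or ""
        mesh_id = img.meta.get("cogmorph_mesh_id", "") or ""
        mask = np.isfinite(values)
    elif path.suffix in (".tsv", ".txt"):
        values, name, mask, mesh_id = _read_tsv(path)
    else:
        raise ValueError(f"unsupported map format: {path.name}")
    mask &= np.isfinite(values)
    if mesh is not None:
        if len(values) != mesh.n_vertices:
            raise MeshMismatchError(
                f"{path.name}: file has {len(values)} vertices but mesh has {mesh.n_vertices}"
            )
        mask &= mesh.cortex_mask
        mesh_id = mesh.mesh_id
    return VertexMap(values, mask, name=name, mesh_id=mesh_id)


def _read_tsv(path: Path) -> tuple[np.ndarray, str, np.ndarray, str]:
    rows: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or (lineno == 1 and line.lower().startswith("vertex")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise MapIOError(f"{path.name}, line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                idx = int(parts[0])
            except ValueError:
                raise MapIOError(
                    f"{path.name}, line {lineno}: non-integer vertex index {parts[0]!r}"
                ) from None
            try:
                val = float(parts[1])
            except ValueError:
                raise MapIOError(
                    f"{path.name}, line {lineno}: non-numeric value {parts[1]!r}"
                ) from None
            rows.append((idx, val))
    if not rows:
        raise MapIOError(f"{path.name}: no data rows")
    n = max(i for i, _ in rows) + 1
    values = np.full(n, np.nan)
    for i, v in rows:
        if i < 0:
            raise MapIOError(f"{path.name}: negative vertex index {i}")
        values[i] = v
    name, mask, mesh_id = _read_sidecar(path, n)
    return values, name, mask, mesh_id


# ----------------------------------------------------------------------------
# Mesh and parcellation containers
# ----------------------------------------------------------------------------

def write_mesh_gifti(path: str | Path, mesh: SphereMesh) -> None:
    """Write mesh geometry as a GIFTI surface (.surf.gii)."""
    coords = nib.gifti.GiftiDataArray(
        mesh.coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    faces = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, faces]), str(path))


def write_annot(path: str | Path, parc: Parcellation) -> None:
    """Write a parcellation in FreeSurfer annot format (whole mesh, 0-based ids)."""
    ids = np.asarray(parc.labels, dtype=int)
    n_regions = max(parc.region_names) + 1
    rng = np.random.default_rng(0)  # fixed colour table; colours are cosmetic
    ctab = np.column_stack(
        [rng.integers(0, 255, size=(n_regions, 3)), np.zeros(n_regions, dtype=int)]
    ).astype(int)
    names = [parc.region_names.get(k, f"region_{k:02d}") for k in range(n_regions)]
    nib.freesurfer.io.write_annot(str(path), ids, ctab, names, fill_ctab=True)


def read_annot(path: str | Path, paired: bool = True) -> Parcellation:
    labels, _, names = nib.freesurfer.io.read_annot(str(path))
    name_table = {
        i: (n.decode() if isinstance(n, bytes) else str(n)) for i, n in enumerate(names)
    }
    return Parcellation(np.asarray(labels, dtype=int), name_table, paired=paired)
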