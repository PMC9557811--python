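"""Reading, writing and curation of 3D landmark datasets.

A dataset is a stack of homologous landmark configurations — one ordered
set of 3D points per specimen — plus a per-specimen factor table (sex,
habitat, site, numeric covariates).  Three text formats are supported:

* ``tps``      — classic TPS blocks (``LM3=`` point count, coordinate rows,
  ``ID=`` / ``IMAGE=`` specimen key)
* ``csv_wide`` — one row per specimen, columns ``<label>_x,<label>_y,<label>_z``
* ``csv_long`` — tidy rows ``specimen,landmark,x,y,z``

Landmarks are 0-based internally; file formats and messages use 1-based
labels, the convention of the morphometrics literature.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkDataset",
    "read_landmarks",
    "write_landmarks",
    "read_factor_table",
    "attach_factors",
    "drop_landmarks",
]

_FORMATS = ("tps", "csv_wide", "csv_long")


class LandmarkFormatError(ValueError):
    """Structural or parse problem in a landmark or factor file."""


@dataclass
class LandmarkDataset:
    """n specimens x p landmarks x 3 coordinates, with factor annotations.

    Parameters
    ----------
    specimen_ids : list of str
        Unique specimen labels, in file/creation order.
    coords : ndarray, shape (n, p, 3)
        Raw landmark coordinates in the digitizing units (e.g. mm).
    landmark_labels : list of str, optional
        One label per landmark; defaults to "1".."p".
    factors : pandas.DataFrame, optional
        Indexed by specimen id; categorical columns such as sex/habitat/site
        and numeric covariates.  Row order matches ``specimen_ids``.
    provenance : list of str
        Human-readable log of curation steps (landmark drops, joins).
    """

    specimen_ids: list[str]
    coords: np.ndarray
    landmark_labels: list[str] | None = None
    factors: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise LandmarkFormatError(
                f"coords must be (n, p, 3); got {self.coords.shape}"
            )
        n, p, _ = self.coords.shape
        if n < 1 or p < 3:
            raise LandmarkFormatError(f"need n >= 1 and p >= 3; got n={n}, p={p}")
        if len(self.specimen_ids) != n:
            raise LandmarkFormatError(
                f"{len(self.specimen_ids)} specimen ids for {n} configurations"
            )
        if len(set(self.specimen_ids)) != n:
            dupes = sorted(
                {s for s in self.specimen_ids if self.specimen_ids.count(s) > 1}
            )
            raise LandmarkFormatError(f"duplicate specimen ids: {dupes}")
        if not np.isfinite(self.coords).all():
            bad = np.argwhere(~np.isfinite(self.coords))[0]
            raise LandmarkFormatError(
                f"non-finite coordinate at specimen {self.specimen_ids[bad[0]]}, "
                f"landmark {bad[1] + 1}"
            )
        if self.landmark_labels is None:
            self.landmark_labels = [str(j + 1) for j in range(p)]
        elif len(self.landmark_labels) != p:
            raise LandmarkFormatError(
                f"{len(self.landmark_labels)} landmark labels for p={p}"
            )
        if self.factors is not None and not self.factors.index.equals(
            pd.Index(self.specimen_ids)
        ):
            raise LandmarkFormatError("factor table rows must match specimen_ids 1:1")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def dim(self) -> int:
        return 3


# ---------------------------------------------------------------------------
# readers


def read_landmarks(path, format: str) -> LandmarkDataset:
    """Read a landmark coordinate file into a :class:`LandmarkDataset`.

    ``format`` is one of ``tps``, ``csv_wide``, ``csv_long``.  All specimens
    must share the same landmark count; a ragged file raises
    :class:`LandmarkFormatError` naming the offending specimen.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "tps":
        return _read_tps(path)
    if format == "csv_wide":
        return _read_csv_wide(path)
    return _read_csv_long(path)


def _read_tps(path) -> LandmarkDataset:
    ids: list[str] = []
    blocks: list[np.ndarray] = []
    cur: list[list[float]] = []
    expected = None
    cur_id = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                if expected is not None:
                    _close_tps_block(ids, blocks, cur, expected, cur_id)
                    cur, cur_id = [], None
                expected = int(line.split("=", 1)[1])
            elif upper.startswith("ID=") or upper.startswith("IMAGE="):
                # prefer ID over IMAGE when both present
                val = line.split("=", 1)[1].strip()
                if cur_id is None or upper.startswith("ID="):
                    cur_id = val
            elif "=" in line and not _looks_numeric(line.split()[0]):
                continue  # SCALE= and friends: ignored
            else:
                parts = line.split()
                try:
                    xyz = [float(v) for v in parts]
                except ValueError:
                    raise LandmarkFormatError(
                        f"{path}: non-numeric coordinate on line {lineno}: {line!r}"
                    ) from None
                if len(xyz) != 3:
                    raise LandmarkFormatError(
                        f"{path}: expected 3 coordinates on line {lineno}, "
                        f"got {len(xyz)}"
                    )
                cur.append(xyz)
    if expected is None:
        raise LandmarkFormatError(f"{path}: no LM3= blocks found")
    _close_tps_block(ids, blocks, cur, expected, cur_id)
    counts = {b.shape[0] for b in blocks}
    if len(counts) > 1:
        bad = ids[[b.shape[0] for b in blocks].index(max(counts))]
        raise LandmarkFormatError(
            f"{path}: ragged landmark counts {sorted(counts)} (see specimen {bad})"
        )
    return LandmarkDataset(ids, np.stack(blocks))


def _close_tps_block(ids, blocks, cur, expected, cur_id) -> None:
    if len(cur) != expected:
        who = cur_id if cur_id is not None else f"block {len(blocks) + 1}"
        raise LandmarkFormatError(
            f"specimen {who}: LM3={expected} but {len(cur)} coordinate rows"
        )
    ids.append(cur_id if cur_id is not None else str(len(blocks) + 1))
    blocks.append(np.array(cur, dtype=float))


def _looks_numeric(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_csv_wide(path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen": str})
    if "specimen" not in df.columns:
        raise LandmarkFormatError(f"{path}: csv_wide needs a 'specimen' column")
    coord_cols = [c for c in df.columns if c != "specimen"]
    labels: list[str] = []
    for c in coord_cols:
        if "_" not in c or c.rsplit("_", 1)[1] not in ("x", "y", "z"):
            raise LandmarkFormatError(
                f"{path}: column {c!r} does not match <label>_x/_y/_z"
            )
        lab = c.rsplit("_", 1)[0]
        if lab not in labels:
            labels.append(lab)
    expected = [f"{lab}_{ax}" for lab in labels for ax in "xyz"]
    missing = set(expected) - set(coord_cols)
    if missing:
        raise LandmarkFormatError(f"{path}: missing coordinate columns {sorted(missing)}")
    arr = df[expected].to_numpy(dtype=float).reshape(len(df), len(labels), 3)
    return LandmarkDataset(df["specimen"].tolist(), arr, landmark_labels=labels)


def _read_csv_long(path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen": str, "landmark": str})
    need = {"specimen", "landmark", "x", "y", "z"}
    if not need.issubset(df.columns):
        raise LandmarkFormatError(
            f"{path}: csv_long needs columns {sorted(need)}, got {list(df.columns)}"
        )
    ids = list(dict.fromkeys(df["specimen"]))
    labels = list(dict.fromkeys(df["landmark"]))
    p = len(labels)
    blocks = []
    for sid, grp in df.groupby("specimen", sort=False):
        if list(grp["landmark"]) != labels:
            if len(grp) != p:
                raise LandmarkFormatError(
                    f"{path}: specimen {sid} has {len(grp)} landmarks, expected {p}"
                )
            grp = grp.set_index("landmark").loc[labels].reset_index()
        blocks.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
    return LandmarkDataset(ids, np.stack(blocks), landmark_labels=labels)


# ---------------------------------------------------------------------------
# writers


def write_landmarks(ds: LandmarkDataset, path, format: str) -> None:
    """Write ``ds`` in the given format. Round-trips bit-for-bit via repr."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "tps":
        buf = io.StringIO()
        for sid, cfg in zip(ds.specimen_ids, ds.coords):
            buf.write(f"LM3={ds.n_landmarks}\n")
            for x, y, z in cfg:
                buf.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
            buf.write(f"ID={sid}\n")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    elif format == "csv_wide":
        cols = {"specimen": ds.specimen_ids}
        for j, lab in enumerate(ds.landmark_labels):
            for k, ax in enumerate("xyz"):
                cols[f"{lab}_{ax}"] = ds.coords[:, j, k]
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        rows = {
            "specimen": np.repeat(ds.specimen_ids, ds.n_landmarks),
            "landmark": np.tile(ds.landmark_labels, ds.n_specimens),
            "x": ds.coords[:, :, 0].ravel(),
            "y": ds.coords[:, :, 1].ravel(),
            "z": ds.coords[:, :, 2].ravel(),
        }
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# factor tables and curation


def read_factor_table(path) -> pd.DataFrame:
    """Read a specimen factor CSV (key column ``specimen_id`` or ``specimen``)."""
    df = pd.read_csv(path, dtype=str)
    key = "specimen_id" if "specimen_id" in df.columns else "specimen"
    if key not in df.columns:
        raise LandmarkFormatError(
            f"{path}: factor table needs a 'specimen_id' (or 'specimen') column"
        )
    if df[key].duplicated().any():
        dupes = df.loc[df[key].duplicated(), key].tolist()
        raise LandmarkFormatError(f"{path}: duplicate specimen keys {dupes}")
    df = df.set_index(key)
    # numeric covariates come back as strings; convert where possible
    for c in df.columns:
        converted = pd.to_numeric(df[c], errors="coerce")
        if converted.notna().all():
            df[c] = converted
    return df


def attach_factors(ds: LandmarkDataset, ft: pd.DataFrame) -> LandmarkDataset:
    """Join a factor table onto a dataset; coordinates are untouched.

    Every specimen id must be present in ``ft``; extra table rows are
    ignored.  Raises on missing ids (listing them) or duplicate keys.
    """
    if ft.index.duplicated().any():
        raise LandmarkFormatError(
            f"duplicate factor keys: {ft.index[ft.index.duplicated()].tolist()}"
        )
    missing = [s for s in ds.specimen_ids if s not in ft.index]
    if missing:
        raise LandmarkFormatError(f"specimens missing from factor table: {missing}")
    joined = ft.loc[ds.specimen_ids].copy()
    return replace(
        ds,
        factors=joined,
        provenance=ds.provenance + [f"attached factors: {list(ft.columns)}"],
    )


def drop_landmarks(ds: LandmarkDataset, indices: list[int]) -> LandmarkDataset:
    """Remove landmarks by 0-based index (e.g. screened-out spine points).

    Labels and coordinates stay co-indexed; the removal is logged in
    ``provenance`` with 1-based labels.
    """
    if len(set(indices)) != len(indices):
        raise ValueError(f"duplicate landmark indices: {sorted(indices)}")
    p = ds.n_landmarks
    bad = [i for i in indices if not (0 <= i < p)]
    if bad:
        raise IndexError(f"landmark indices out of range [0, {p}): {bad}")
    if not indices:
        return ds
    keep = [j for j in range(p) if j not in set(indices)]
    dropped = [ds.landmark_labels[i] for i in sorted(indices)]
    return replace(
        ds,
        coords=ds.coords[:, keep, :],
        landmark_labels=[ds.landmark_labels[j] for j in keep],
        provenance=ds.provenance + [f"dropped landmarks (1-based labels): {dropped}"],
    )
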