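"""Library-scale screening: rank every model of a library against a target.

A screen runs the full rigid-body search once per model (best pose only, so
a model appearing under several orientations collapses to a single row),
sorts by normalized cross-correlation and reports a deduplicated
:class:`RankTable`.  Models that fail to read or fit are skipped with a
warning and listed on the table — a 20,000-model screen must not die on one
bad file.  Output ordering is defined entirely by the sort (score, then
unnormalized score, then model id), never by completion or file order.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .fitcore import FitParams, FitResult, Pose, fit_model
from .grid import VoxelGrid
from .model import AtomicModel, read_model

logger = logging.getLogger(__name__)

MODEL_SUFFIXES = (".pdb", ".ent", ".cif", ".mmcif")


@dataclasses.dataclass
class RankRow:
    rank: int
    model_id: str
    cc_normalized: float
    cc_unnormalized: float
    pose: Pose
    n_atoms: int


@dataclasses.dataclass
class RankTable:
    """Deduplicated, score-sorted library hits with the parameters echoed."""

    rows: list[RankRow]
    params_echo: FitParams
    skipped: list[str] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def rank_of(self, model_id: str) -> int:
        for row in self.rows:
            if row.model_id == model_id:
                return row.rank
        raise KeyError(f"model {model_id!r} not in table")

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "rank": r.rank,
                "model_id": r.model_id,
                "cc_normalized": r.cc_normalized,
                "cc_unnormalized": r.cc_unnormalized,
                "n_atoms": r.n_atoms,
                "mirrored": int(r.pose.mirrored),
            }
            for i in range(3):
                for j in range(3):
                    rec[f"r{i}{j}"] = r.pose.rotation[i, j]
            for ax, name in enumerate(("tx", "ty", "tz")):
                rec[name] = r.pose.translation[ax]
            recs.append(rec)
        return pd.DataFrame.from_records(recs)


def _iter_models(library):
    """Yield AtomicModels from a directory, a list of paths, or models."""
    if isinstance(library, (str, Path)):
        root = Path(library)
        if not root.is_dir():
            raise ValueError(f"library directory not found: {root}")
        paths = sorted(
            p for p in root.rglob("*")
            if p.suffix.lower() in MODEL_SUFFIXES and p.is_file()
        )
        if not paths:
            raise ValueError(f"no model files under {root}")
        for p in paths:
            yield p
        return
    items = list(library)
    if not items:
        raise ValueError("empty model library")
    yield from items


def scan_library(library, target: VoxelGrid,
                 params: FitParams | None = None) -> RankTable:
    """Fit every model of a library and rank the best poses.

    ``library`` is a directory of PDB/mmCIF files (searched recursively, in
    sorted order so file-system order never matters) or an iterable of
    :class:`AtomicModel`.  One row per model id; unreadable or unfittable
    entries are skipped with a warning and listed in ``table.skipped``.
    """
    if params is None:
        params = FitParams()
    results: list[FitResult] = []
    skipped: list[str] = []
    for item in _iter_models(library):
        name = str(item) if isinstance(item, Path) else item.model_id
        t0 = time.perf_counter()
        try:
            model = read_model(item) if isinstance(item, Path) else item
            results.append(fit_model(target, model, params))
        except (ValueError, OSError) as exc:
            warnings.warn(f"skipping model {name}: {exc}", stacklevel=2)
            skipped.append(name)
            continue
        logger.info("fit %s: cc=%.4f (%.2fs)", results[-1].model_id,
                    results[-1].cc_normalized, time.perf_counter() - t0)
    if not results:
        raise ValueError("no model in the library could be scored")
    # best pose per model id (dedup), then deterministic sort
    by_id: dict[str, FitResult] = {}
    for r in results:
        prev = by_id.get(r.model_id)
        if prev is None or (r.cc_normalized, r.cc_unnormalized) > (
            prev.cc_normalized, prev.cc_unnormalized
        ):
            by_id[r.model_id] = r
    ordered = sorted(
        by_id.values(),
        key=lambda r: (-r.cc_normalized, -r.cc_unnormalized, r.model_id),
    )
    rows = [
        RankRow(i + 1, r.model_id, r.cc_normalized, r.cc_unnormalized,
                r.pose, r.n_atoms)
        for i, r in enumerate(ordered)
    ]
    return RankTable(rows, params, skipped)


def top_hits(table: RankTable, n: int) -> RankTable:
    """First min(n, len) rows, ranks preserved."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return RankTable(table.rows[:n], table.params_echo,
                     list(table.skipped))


def validate_control(target: VoxelGrid, library, expected_id: str,
                     params: FitParams | None = None) -> int:
    """1-based rank of a known control model in the library screen.

    Raises if ``expected_id`` is not in the library (or could not be
    scored).  The screening protocol counts a control as validated when the
    expected model comes up as the top hit.
    """
    table = scan_library(library, target, params)
    try:
        return table.rank_of(expected_id)
    except KeyError:
        raise ValueError(
            f"expected model {expected_id!r} not present in the library "
            f"(skipped: {table.skipped})"
        ) from None


def occupancy_ratio(map_a: VoxelGrid, map_b: VoxelGrid,
                    feature_mask: VoxelGrid,
                    reference_mask: VoxelGrid) -> float:
    """Reference-normalized relative occupancy of a feature in map_b vs map_a.

    Returns (mean_b(feature) / mean_b(reference)) divided by
    (mean_a(feature) / mean_a(reference)).  Mask grids are boolean via
    value > 0.5; means (not integrals) are used so mask voxel counts cancel.
    A feature that kept its density in both maps gives 1.0; a knockout that
    empties the feature while the reference stays put gives the scaling
    factor directly.
    """
    grids = (map_a, map_b, feature_mask, reference_mask)
    dims = {g.dims for g in grids}
    if len(dims) != 1:
        raise ValueError(f"grids not commensurate: dims {sorted(dims)}")
    for g in grids[1:]:
        if abs(g.voxel_size - map_a.voxel_size) > 1e-6 * map_a.voxel_size:
            raise ValueError("voxel size mismatch between grids")
    feat = feature_mask.values > 0.5
    ref = reference_mask.values > 0.5
    if not feat.any():
        raise ValueError("feature mask is empty")
    if not ref.any():
        raise ValueError("reference mask is empty")
    a_feat = map_a.values[feat].mean()
    a_ref = map_a.values[ref].mean()
    b_feat = map_b.values[feat].mean()
    b_ref = map_b.values[ref].mean()
    if a_feat == 0 or a_ref == 0 or b_ref == 0:
        raise ValueError("zero mean density under a mask; ratio undefined")
    return float((b_feat / b_ref) / (a_feat / a_ref))


# ---------------------------------------------------------------------------
# rank-table serialization

_POSE_COLS = [f"r{i}{j}" for i in range(3) for j in range(3)] + [
    "tx", "ty", "tz"
]


def write_rank_table(table: RankTable, path) -> None:
    """TSV with fixed column order; parameters echoed as comment lines.

    Poses are serialized as 12 numbers: row-major rotation matrix followed
    by the translation in Å.
    """
    if not table.rows:
        raise ValueError("refusing to write an empty rank table")
    p = table.params_echo
    lines = [
        "# voxmatch rank table",
        (f"# resolution={p.resolution:g} cutoff={p.cutoff:g} "
         f"step_deg={p.step_deg:g} mode={p.mode} mirror={p.mirror} "
         f"weight_mode={p.weight_mode}"),
    ]
    if table.skipped:
        lines.append("# skipped=" + ",".join(table.skipped))
    df = table.to_dataframe()
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g",
                  lineterminator="\n")


def read_rank_table(path) -> RankTable:
    """Read a TSV written by :func:`write_rank_table`."""
    header: dict[str, str] = {}
    skipped: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("skipped="):
                skipped = body[len("skipped="):].split(",")
            else:
                for tok in body.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
    df = pd.read_csv(path, sep="\t", comment="#")
    params = FitParams(
        resolution=float(header.get("resolution", 6.0)),
        step_deg=float(header.get("step_deg", 15.0)),
        cutoff=float(header.get("cutoff", 0.0)),
        mode=header.get("mode", "standard"),
        mirror=header.get("mirror", "False") == "True",
        weight_mode=header.get("weight_mode", "unit"),
    )
    rows = []
    for rec in df.itertuples(index=False):
        rot = np.array([getattr(rec, f"r{i}{j}") for i in range(3)
                        for j in range(3)]).reshape(3, 3)
        t = np.array([rec.tx, rec.ty, rec.tz])
        rows.append(
            RankRow(int(rec.rank), str(rec.model_id),
                    float(rec.cc_normalized), float(rec.cc_unnormalized),
                    Pose(rot, t, bool(rec.mirrored)), int(rec.n_atoms))
        )
    return RankTable(rows, params, skipped)
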