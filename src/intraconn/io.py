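"""Readers and writers for all on-disk formats.

Formats: OFF/PLY meshes plus a TSV label table; streamlines as TCK or a
plain TSV-of-points dialect; connectomes as Matrix Market sparse matrices
with a node table TSV; metric tables and cohort files as TSV/CSV; ground
truth and reports as JSON; configuration as YAML.

Every table this package writes starts with comment lines naming the
producing stage, the configuration hash and the seed.  Node and region
indices are 0-based in memory and written 1-based in tables (stated in the
file headers).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .connectome import HighResConnectome, LowResConnectome
from .metrics import MetricTable
from .synthetic import StreamlineSet, SubjectRecord, SurfaceMesh

__all__ = [
    "ParseError",
    "write_mesh", "read_mesh",
    "write_streamlines_tsv", "read_streamlines_tsv",
    "write_streamlines_tck", "read_streamlines_tck",
    "write_connectome", "read_connectome",
    "write_lowres", "read_lowres",
    "write_cohort_csv", "read_cohort_csv",
    "write_metric_table", "read_metric_table",
    "write_ground_truth", "read_ground_truth",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and the violated rule."""


def _header(stage: str, seed=None, config_hash=None) -> str:
    parts = [f"# stage={stage}"]
    if config_hash is not None:
        parts.append(f"# config_hash={config_hash}")
    if seed is not None:
        parts.append(f"# seed={seed}")
    parts.append("# indices are 1-based in this file")
    return "\n".join(parts) + "\n"


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path, fmt: str = "off", stage: str = "mesh",
               seed=None) -> None:
    """Write geometry as OFF or PLY plus a ``<path>.labels.tsv`` table."""
    import trimesh

    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    data = tm.export(file_type=fmt)
    if isinstance(data, str):
        path.write_text(data)
    else:
        path.write_bytes(data)
    labels = path.with_suffix(path.suffix + ".labels.tsv")
    with open(labels, "w") as fh:
        fh.write(_header(stage, seed=seed))
        fh.write("triangle_index\tregion_id\themisphere\n")
        for i, (g, h) in enumerate(zip(mesh.region_label, mesh.hemisphere)):
            fh.write(f"{i + 1}\t{int(g) + 1}\t{h}\n")


def read_mesh(path) -> SurfaceMesh:
    import trimesh

    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: mesh file not found")
    tm = trimesh.load(str(path), process=False)
    labels_path = path.with_suffix(path.suffix + ".labels.tsv")
    if not labels_path.exists():
        raise ParseError(f"{labels_path}: label table not found")
    tab = pd.read_csv(labels_path, sep="\t", comment="#")
    needed = {"triangle_index", "region_id", "hemisphere"}
    if not needed.issubset(tab.columns):
        raise ParseError(f"{labels_path}: missing columns {needed - set(tab.columns)}")
    if len(tab) != len(tm.faces):
        raise ParseError(
            f"{labels_path}: {len(tab)} labels for {len(tm.faces)} triangles")
    order = np.argsort(tab.triangle_index.to_numpy())
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       tab.region_id.to_numpy()[order] - 1,
                       tab.hemisphere.to_numpy()[order])


# ---------------------------------------------------------------------------
# Streamlines
# ---------------------------------------------------------------------------

def write_streamlines_tsv(streamlines: StreamlineSet, path,
                          stage: str = "streamlines", seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, seed=seed))
        fh.write("streamline_id\tpoint_index\tx\ty\tz\n")
        for i in range(streamlines.n):
            for j, p in enumerate(streamlines[i]):
                fh.write(f"{i + 1}\t{j + 1}\t{p[0]:.12g}\t{p[1]:.12g}\t{p[2]:.12g}\n")


def read_streamlines_tsv(path) -> StreamlineSet:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: streamline file not found")
    tab = pd.read_csv(path, sep="\t", comment="#")
    needed = {"streamline_id", "point_index", "x", "y", "z"}
    if not needed.issubset(tab.columns):
        raise ParseError(f"{path}: missing columns {needed - set(tab.columns)}")
    tab = tab.sort_values(["streamline_id", "point_index"])
    polys = [g[["x", "y", "z"]].to_numpy()
             for _, g in tab.groupby("streamline_id", sort=True)]
    return StreamlineSet.from_polylines(polys)


def write_streamlines_tck(streamlines: StreamlineSet, path) -> None:
    import nibabel as nib
    from nibabel.streamlines import Tractogram

    tract = Tractogram([streamlines[i] for i in range(streamlines.n)],
                       affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tract, str(path))


def read_streamlines_tck(path) -> StreamlineSet:
    import nibabel as nib

    obj = nib.streamlines.load(str(path))
    return StreamlineSet.from_polylines(
        [np.asarray(s, dtype=float) for s in obj.streamlines])


# ---------------------------------------------------------------------------
# Connectomes
# ---------------------------------------------------------------------------

def write_connectome(conn: HighResConnectome, outdir, prefix: str = "highres",
                     stage: str = "connectome", seed=None) -> None:
    """MTX count/weight matrices plus a node table and length lists."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp.save_npz  # noqa: B018 -- MTX chosen for text-only portability
    from scipy.io import mmwrite

    mmwrite(outdir / f"{prefix}_counts.mtx", sp.coo_matrix(conn.counts))
    mmwrite(outdir / f"{prefix}_weights.mtx", sp.coo_matrix(conn.weights))
    with open(outdir / f"{prefix}_nodes.tsv", "w") as fh:
        fh.write(_header(stage, seed=seed))
        fh.write("node_id\tregion_id\themisphere\tarea_mm2\tx\ty\tz\n")
        for i in range(conn.n_nodes):
            c = conn.node_center[i]
            fh.write(f"{i + 1}\t{int(conn.node_region[i]) + 1}\t"
                     f"{conn.node_hemisphere[i]}\t{conn.node_area[i]:.12g}\t"
                     f"{c[0]:.12g}\t{c[1]:.12g}\t{c[2]:.12g}\n")
    lengths = {str(int(k) + 1): np.asarray(v).tolist()
               for k, v in conn.intra_region_lengths.items()}
    (outdir / f"{prefix}_lengths.json").write_text(json.dumps(lengths))


def read_connectome(outdir, prefix: str = "highres") -> HighResConnectome:
    from scipy.io import mmread

    outdir = Path(outdir)
    counts = sp.csr_matrix(mmread(outdir / f"{prefix}_counts.mtx"))
    weights = sp.csr_matrix(mmread(outdir / f"{prefix}_weights.mtx"))
    tab = pd.read_csv(outdir / f"{prefix}_nodes.tsv", sep="\t", comment="#")
    order = np.argsort(tab.node_id.to_numpy())
    tab = tab.iloc[order]
    lengths_file = outdir / f"{prefix}_lengths.json"
    lengths = {}
    if lengths_file.exists():
        raw = json.loads(lengths_file.read_text())
        lengths = {int(k) - 1: np.asarray(v, dtype=float)
                   for k, v in raw.items()}
    return HighResConnectome(
        counts=counts, weights=weights,
        node_region=tab.region_id.to_numpy() - 1,
        node_center=tab[["x", "y", "z"]].to_numpy(),
        node_area=tab.area_mm2.to_numpy(),
        node_hemisphere=tab.hemisphere.to_numpy(),
        intra_region_lengths=lengths)


def write_lowres(low: LowResConnectome, outdir, stage: str = "connectome",
                 seed=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, mat in (("counts", low.counts), ("weights", low.weights)):
        with open(outdir / f"lowres_{name}.tsv", "w") as fh:
            fh.write(_header(stage, seed=seed))
            pd.DataFrame(mat, index=low.region_ids + 1,
                         columns=low.region_ids + 1).to_csv(fh, sep="\t")


def read_lowres(outdir) -> LowResConnectome:
    outdir = Path(outdir)
    counts = pd.read_csv(outdir / "lowres_counts.tsv", sep="\t", comment="#",
                         index_col=0)
    weights = pd.read_csv(outdir / "lowres_weights.tsv", sep="\t",
                          comment="#", index_col=0)
    region_ids = counts.index.to_numpy().astype(int) - 1
    return LowResConnectome(counts.to_numpy(), weights.to_numpy(), region_ids)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = ["id", "group", "age", "sex", "side", "duration",
                   "outcome", "assigned_side"]


def write_cohort_csv(records, path, stage: str = "cohort", seed=None) -> None:
    from .synthetic import cohort_dataframe

    df = cohort_dataframe(records)
    with open(path, "w") as fh:
        fh.write(_header(stage, seed=seed))
        df.to_csv(fh, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Cohort table with per-row validation.

    Raises :class:`ParseError` naming the offending row when a patient is
    missing its surgery side, duration or outcome.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: cohort file not found")
    df = pd.read_csv(path, comment="#")
    missing = set(_COHORT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("side", "duration", "outcome", "assigned_side"):
        if col not in df.columns:
            df[col] = None
    for i, row in df.iterrows():
        try:
            SubjectRecord(
                id=str(row["id"]), group=str(row["group"]),
                age=float(row["age"]), sex=str(row["sex"]),
                side="none" if pd.isna(row["side"]) else str(row["side"]),
                duration=None if pd.isna(row["duration"]) else float(row["duration"]),
                outcome=None if pd.isna(row["outcome"]) else int(row["outcome"]),
                assigned_side="L" if pd.isna(row["assigned_side"])
                else str(row["assigned_side"]))
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    df["side"] = df["side"].fillna("none")
    return df


# ---------------------------------------------------------------------------
# Metric tables and reports
# ---------------------------------------------------------------------------

def write_metric_table(table: MetricTable, path, stage: str = "metrics",
                       seed=None, cfg_hash=None) -> None:
    data = table.data.copy()
    data["flag"] = np.where(data.value.isna(), "missing", "ok")
    with open(path, "w") as fh:
        fh.write(_header(stage, seed=seed, config_hash=cfg_hash))
        counts = json.dumps(table.node_counts)
        fh.write(f"# node_counts={counts}\n")
        data.to_csv(fh, sep="\t", index=False)


def read_metric_table(path) -> MetricTable:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: metric table not found")
    node_counts = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# node_counts="):
                node_counts = json.loads(line.split("=", 1)[1])
    data = pd.read_csv(path, sep="\t", comment="#")
    needed = {"subject", "region", "metric", "value"}
    if not needed.issubset(data.columns):
        raise ParseError(f"{path}: missing columns {needed - set(data.columns)}")
    return MetricTable(data[["subject", "region", "metric", "value"]],
                       {k: int(v) for k, v in node_counts.items()})


def write_ground_truth(truth, path) -> None:
    payload = {
        "affected_regions": {s: {str(r): v for r, v in d.items()}
                             for s, d in truth.affected_regions.items()},
        "duration_regions": truth.duration_regions,
        "outcome_regions": truth.outcome_regions,
        "duration_slope": truth.duration_slope,
        "baseline_rate": truth.baseline_rate,
        "flip_side": truth.flip_side,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path):
    from .synthetic import EffectGroundTruth

    raw = json.loads(Path(path).read_text())
    return EffectGroundTruth(
        affected_regions={s: {int(r): v for r, v in d.items()}
                          for s, d in raw["affected_regions"].items()},
        duration_regions={s: list(map(int, v))
                          for s, v in raw["duration_regions"].items()},
        outcome_regions={s: list(map(int, v))
                         for s, v in raw["outcome_regions"].items()},
        duration_slope=raw["duration_slope"],
        baseline_rate=raw["baseline_rate"],
        flip_side=raw["flip_side"])
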