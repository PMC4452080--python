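"""Readers and writers for the pipeline's plain-text formats and TIFFs.

All tabular formats are simple CSV/TSV so generator output and
image-derived output share a schema and downstream stages are
source-agnostic.  Voltammogram and kinetics files carry a ``#
key=value`` metadata header.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .echem import KineticsSeries, Segment, Voltammogram
from .expression import ExpressionMatrix
from .simulate.nuclei import NucleiImage
from .tracking import Trajectory

__all__ = [
    "write_nuclei", "read_nuclei",
    "write_trajectories", "read_trajectories",
    "write_voltammogram", "read_voltammogram",
    "write_kinetics", "read_kinetics",
    "write_expression", "read_expression",
    "write_nuclei_tiff", "read_nuclei_tiff",
    "write_newick",
]


def write_nuclei(records: pd.DataFrame, path) -> None:
    records[["chip", "x_um", "y_um", "labeled"]].to_csv(path, index=False)


def read_nuclei(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["labeled"] = df["labeled"].astype(bool)
    return df


def write_trajectories(trajectories, path) -> None:
    rows = []
    for traj in trajectories:
        for t, x, y in zip(traj.t, traj.x, traj.y):
            rows.append(
                {"cell_id": traj.cell_id, "t_hr": t, "x_um": x, "y_um": y,
                 "condition": traj.condition or ""}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_hr")
        cond = None
        if "condition" in grp and not grp["condition"].isna().all():
            first = grp["condition"].iloc[0]
            cond = str(first) if str(first) else None
        out.append(
            Trajectory(
                cell_id=str(cell_id),
                t=grp["t_hr"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy(),
                condition=cond,
            )
        )
    return out


def write_voltammogram(vgram: Voltammogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scan_rate_mV_s={vgram.scan_rate}\n")
        fh.write(f"# area_cm2={vgram.electrode_area}\n")
        fh.write(f"# reference_electrode={vgram.reference_electrode}\n")
        fh.write("potential_mV,current_uA,direction\n")
        for seg in vgram.segments:
            for e, i in zip(seg.potential_mV, seg.current_uA):
                fh.write(f"{e:.6g},{i:.9g},{seg.direction}\n")


def _read_metadata(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_voltammogram(path) -> Voltammogram:
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    segments = []
    for direction, grp in df.groupby("direction", sort=False):
        segments.append(
            Segment(
                potential_mV=grp["potential_mV"].to_numpy(),
                current_uA=grp["current_uA"].to_numpy(),
                direction=str(direction),
            )
        )
    return Voltammogram(
        segments=segments,
        scan_rate=float(meta.get("scan_rate_mV_s", 50.0)),
        electrode_area=float(meta.get("area_cm2", 1.0)),
        reference_electrode=meta.get("reference_electrode", "Ag/AgCl"),
    )


def write_kinetics(series: KineticsSeries, path) -> None:
    pd.DataFrame({"t_min": series.t_min, "fraction": series.fraction}).to_csv(path, index=False)


def read_kinetics(path) -> KineticsSeries:
    df = pd.read_csv(path, comment="#")
    return KineticsSeries(t_min=df["t_min"].to_numpy(), fraction=df["fraction"].to_numpy())


def write_expression(matrix: ExpressionMatrix, matrix_path, samples_path) -> None:
    """Gene x array TSV with two channel blocks, plus a sample sheet TSV."""
    sample = matrix.sample.add_prefix("sample:")
    reference = matrix.reference.add_prefix("reference:")
    pd.concat([sample, reference], axis=1).to_csv(matrix_path, sep="\t")
    matrix.samples.to_csv(samples_path, sep="\t")


def read_expression(matrix_path, samples_path) -> ExpressionMatrix:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sample_cols = [c for c in df.columns if c.startswith("sample:")]
    ref_cols = [c for c in df.columns if c.startswith("reference:")]
    sample = df[sample_cols].rename(columns=lambda c: c.split(":", 1)[1])
    reference = df[ref_cols].rename(columns=lambda c: c.split(":", 1)[1])
    sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionMatrix(sample=sample, reference=reference, samples=sheet)


def write_nuclei_tiff(image: NucleiImage, path) -> None:
    """Two-channel 16-bit TIFF (channel 0 DAPI, channel 1 BrdU)."""
    stack = np.stack([image.dapi, image.brdu]).clip(0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        stack,
        metadata={
            "pixel_size_um": image.pixel_size,
            "origin_x_um": image.origin[0],
            "origin_y_um": image.origin[1],
        },
    )


def read_nuclei_tiff(path, pixel_size: float | None = None) -> NucleiImage:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    px = pixel_size if pixel_size is not None else float(meta.get("pixel_size_um", 1.0))
    origin = (float(meta.get("origin_x_um", 0.0)), float(meta.get("origin_y_um", 0.0)))
    return NucleiImage(dapi=stack[0].astype(float), brdu=stack[1].astype(float),
                       pixel_size=px, origin=origin)


def write_newick(linkage: np.ndarray, labels, path) -> None:
    """Serialize a scipy linkage tree as a newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(linkage)
    labels = list(labels)

    def walk(node, parent_dist) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    with open(path, "w") as fh:
        fh.write(walk(tree, tree.dist) + ";\n")
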