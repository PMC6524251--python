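"""Plain-text readers and writers for the pipeline's file formats.

Betas, detection-p and bead-count matrices are TSV with probe rows and
sample columns; sample sheets are CSV indexed by sample id; the CpG map is
BED-like TSV (chrom, 0-based start, end, probe_id); DMRs are written both as
BED (0-based half-open) and as an annotated TSV with 1-based inclusive
coordinates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import CpGMap, DMR, MethylationDataset
from .dmr import dmrs_to_frame

__all__ = [
    "read_matrix_tsv", "write_matrix_tsv", "read_sample_sheet",
    "write_sample_sheet", "read_map_bed", "write_map_bed", "read_assoc",
    "write_assoc", "write_dmrs_bed", "write_dmrs_tsv", "read_probe_list",
    "read_weights", "read_dataset",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")


def write_map_bed(cpg_map: CpGMap, path) -> None:
    bed = pd.DataFrame({
        "chrom": cpg_map.table["chrom"],
        "start": cpg_map.table["pos"] - 1,  # 0-based half-open
        "end": cpg_map.table["pos"],
        "probe_id": cpg_map.table["probe_id"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_map_bed(path) -> CpGMap:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "probe_id"])
    return CpGMap(pd.DataFrame({
        "probe_id": bed["probe_id"], "chrom": bed["chrom"],
        "pos": bed["end"],  # back to 1-based
    }))


def read_assoc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_assoc(assoc: pd.DataFrame, path) -> None:
    assoc.to_csv(path, sep="\t", index_label="probe_id")


def write_dmrs_bed(dmrs: list[DMR], path) -> None:
    """BED6: chrom, start, end, name, score (-log10 region p), strand '.'.
    Coordinates are 0-based half-open."""
    import numpy as np
    rows = []
    for i, d in enumerate(dmrs, start=1):
        score = float(-np.log10(max(d.p_region, 1e-300)))
        rows.append((d.chrom, d.start, d.end, f"DMR{i}", f"{score:.4f}", "."))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_dmrs_tsv(dmrs: list[DMR], path) -> None:
    """Annotated table with 1-based inclusive coordinates (stated in header)."""
    frame = dmrs_to_frame(dmrs)
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_probe_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_weights(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=pd.Index(df.iloc[:, 0].astype(str), name="probe_id"),
                     name="weight")


def read_dataset(betas_path, sheet_path, map_path) -> MethylationDataset:
    return MethylationDataset(betas=read_matrix_tsv(betas_path),
                              sample_sheet=read_sample_sheet(sheet_path),
                              cpg_map=read_map_bed(map_path))
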