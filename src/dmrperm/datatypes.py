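"""Core containers shared by the two-arm differential-methylation pipeline.

Conventions used throughout the package:

* methylation matrices are probes x samples DataFrames of beta values in (0, 1);
* genomic positions are 1-based in :class:`CpGMap` (as printed in array
  manifests) and 0-based half-open on :class:`DMR` intervals (as written to BED);
* ``direction`` is ``"hypo"`` for a negative mean beta difference
  (exposed/deprived minus control) and ``"hyper"`` otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGMap",
    "EffectSpec",
    "CellReference",
    "MethylationDataset",
    "QCReport",
    "DMR",
    "OverlapPair",
    "PermutationResult",
]


def _chrom_sort_key(chrom: str):
    """Natural ordering: chr1 < chr2 < ... < chr10 < chrX."""
    m = re.match(r"(?:chr)?(\d+)$", str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom))


class CpGMap:
    """Ordered CpG probe coordinates defining the shared genome of an analysis.

    Parameters
    ----------
    table : DataFrame with columns ``probe_id``, ``chrom``, ``pos``.
        Positions are 1-based. Rows are sorted by (chromosome, position) and an
        ``order_index`` column (rank of the probe within its chromosome) is
        added. Probe ids must be unique and positions strictly increasing
        within each chromosome.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"CpGMap table missing columns: {sorted(missing)}")
        df = table.loc[:, ["probe_id", "chrom", "pos"]].copy()
        df["probe_id"] = df["probe_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based coordinates)")
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].head().tolist()
            raise ValueError(f"duplicate probe ids: {dups}")
        chrom_rank = {c: i for i, c in
                      enumerate(sorted(df["chrom"].unique(), key=_chrom_sort_key))}
        order = np.lexsort((df["pos"].to_numpy(),
                            df["chrom"].map(chrom_rank).to_numpy()))
        df = df.iloc[order].reset_index(drop=True)
        order = df.groupby("chrom", sort=False).cumcount()
        df["order_index"] = order
        for _, grp in df.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")
        self.table = df
        self._index_of = pd.Series(np.arange(len(df)), index=df["probe_id"].to_numpy())

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Global (iloc) slice of the rows on one chromosome."""
        mask = (self.table["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def indices_of(self, probe_ids: Sequence[str]) -> np.ndarray:
        """Global row indices of the given probes (raises on unknown ids)."""
        try:
            return self._index_of.loc[list(probe_ids)].to_numpy()
        except KeyError as exc:
            raise KeyError(f"probe ids absent from map: {exc}") from exc

    def subset(self, probe_ids: Sequence[str]) -> "CpGMap":
        """New map restricted to the given probes (original order retained)."""
        keep = set(map(str, probe_ids))
        sub = self.table[self.table["probe_id"].isin(keep)]
        if sub.empty:
            raise ValueError("subset would leave an empty map")
        return CpGMap(sub[["probe_id", "chrom", "pos"]])

    @classmethod
    def from_arrays(cls, probe_id, chrom, pos) -> "CpGMap":
        return cls(pd.DataFrame({"probe_id": probe_id, "chrom": chrom, "pos": pos}))

    def equals(self, other: "CpGMap") -> bool:
        return self.table.equals(other.table)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CpGMap({len(self)} probes, {len(self.chromosomes)} chromosomes)"


@dataclass(frozen=True)
class EffectSpec:
    """A contiguous spiked effect region for the synthetic generators.

    ``start`` is the 0-based order index of the first CpG within ``chrom``;
    ``delta_m`` is the additive shift on the M scale applied to
    exposed/deprived samples. Direction follows the sign of ``delta_m``.
    """

    chrom: str
    start: int
    n_cpgs: int
    delta_m: float

    def __post_init__(self):
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if self.delta_m == 0:
            raise ValueError("delta_m must be nonzero (direction undefined)")

    @property
    def direction(self) -> str:
        return "hypo" if self.delta_m < 0 else "hyper"

    def global_indices(self, cpg_map: CpGMap) -> np.ndarray:
        sl = cpg_map.chrom_slice(self.chrom)
        n_chrom = sl.stop - sl.start
        if self.start < 0 or self.start + self.n_cpgs > n_chrom:
            raise ValueError(
                f"effect region {self.chrom}:{self.start}+{self.n_cpgs} outside map "
                f"({n_chrom} probes on {self.chrom})"
            )
        return np.arange(sl.start + self.start, sl.start + self.start + self.n_cpgs)


@dataclass(frozen=True)
class CellReference:
    """Reference methylation profiles (probes x cell types, beta scale)."""

    profiles: pd.DataFrame

    def __post_init__(self):
        if self.profiles.shape[1] < 2:
            raise ValueError("a cell reference needs at least two cell types")
        vals = self.profiles.to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("reference profiles must lie in [0, 1]")

    @property
    def cell_names(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.profiles.index


@dataclass
class MethylationDataset:
    """A beta matrix with its sample sheet and CpG map.

    ``betas`` is probes x samples; ``sample_sheet`` has one row per sample
    (index = sample id, matching the beta columns 1:1).
    """

    betas: pd.DataFrame
    sample_sheet: pd.DataFrame
    cpg_map: CpGMap

    def __post_init__(self):
        if not self.betas.columns.equals(self.sample_sheet.index):
            raise ValueError("beta columns and sample sheet rows must match 1:1")
        if not set(self.betas.index) <= set(self.cpg_map.probe_ids):
            raise ValueError("beta matrix contains probes absent from the map")
        # keep probe rows in map order
        order = [p for p in self.cpg_map.probe_ids if p in set(self.betas.index)]
        self.betas = self.betas.loc[order]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]


_EXCLUSION_REASONS = ("bead", "detection", "blacklist")


@dataclass
class QCReport:
    """Outcome of probe/sample filtering.

    ``exclusions`` maps excluded probe id -> reason, with the bead-count rule
    taking precedence over detection, and detection over blacklist, when a
    probe trips several rules.
    """

    kept_probes: list[str]
    exclusions: dict[str, str]
    failed_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        bad = set(self.exclusions.values()) - set(_EXCLUSION_REASONS)
        if bad:
            raise ValueError(f"unknown exclusion reasons: {sorted(bad)}")
        if set(self.kept_probes) & set(self.exclusions):
            raise ValueError("a probe cannot be both kept and excluded")

    def _count(self, reason: str) -> int:
        return sum(1 for r in self.exclusions.values() if r == reason)

    @property
    def excluded_bead(self) -> int:
        return self._count("bead")

    @property
    def excluded_detection(self) -> int:
        return self._count("detection")

    @property
    def excluded_blacklist(self) -> int:
        return self._count("blacklist")

    def summary(self) -> dict:
        return {
            "n_kept": len(self.kept_probes),
            "excluded_bead": self.excluded_bead,
            "excluded_detection": self.excluded_detection,
            "excluded_blacklist": self.excluded_blacklist,
            "failed_samples": list(self.failed_samples),
        }


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region: a run of consecutive map probes.

    ``start``/``end`` are 0-based half-open base coordinates spanning the
    first through last probe (BED convention); :meth:`span_1based` gives the
    1-based inclusive form used in reports.
    """

    chrom: str
    start: int
    end: int
    probe_ids: tuple
    stat: float
    p_region: float
    mean_delta_beta: float
    direction: str

    def __post_init__(self):
        if self.direction not in ("hypo", "hyper"):
            raise ValueError("direction must be 'hypo' or 'hyper'")
        if self.end <= self.start:
            raise ValueError("end must exceed start (half-open interval)")
        if len(self.probe_ids) < 1:
            raise ValueError("a DMR needs at least one probe")

    @property
    def n_cpgs(self) -> int:
        return len(self.probe_ids)

    def span_1based(self) -> tuple[int, int]:
        return (self.start + 1, self.end)

    def overlaps(self, other: "DMR") -> int:
        """Overlap length in bp under half-open arithmetic (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class OverlapPair:
    """A pair of DMRs from the two arms with >= 1 bp genomic intersection."""

    dmr_a: DMR
    dmr_b: DMR
    overlap_bp: int
    concordant: bool


@dataclass(frozen=True)
class PermutationResult:
    """Empirical p value with its provenance.

    * ``sampled`` mode: add-one estimator, p = (1 + n_as_extreme)/(n_draws + 1).
    * ``exhaustive`` mode: p = n_as_extreme/n_draws with the observed window
      included in its own universe, so p >= 1/n_draws.
    """

    observed: float
    n_as_extreme: int
    n_draws: int
    empirical_p: float
    mode: str
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("exhaustive", "sampled"):
            raise ValueError("mode must be 'exhaustive' or 'sampled'")
        if self.mode == "sampled":
            expect = (1 + self.n_as_extreme) / (self.n_draws + 1)
        else:
            expect = self.n_as_extreme / self.n_draws
        if abs(self.empirical_p - expect) > 1e-12:
            raise ValueError("empirical_p inconsistent with counts for mode")
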