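"""Per-tumor-unique insertion catalogs.

The CIS statistic counts *unique* insertions, so mapped junction reads must
first be collapsed within each tumor: sites from one tumor on one strand
whose positions chain together within a small tolerance (end-trimming jitter,
PCR duplicates) merge into a single insertion at the support-weighted modal
position.  Sites from different tumors never merge — recurrence across
tumors is exactly the signal being tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .readproc import MappedSite

CATALOG_COLUMNS = ["chrom", "pos", "strand", "tumor_id", "specimens", "read_support"]


@dataclass
class InsertionCatalog:
    """Deduplicated insertion sites, sorted by (chrom, pos).

    ``df`` columns: chrom, pos (0-based junction), strand, tumor_id,
    specimens (comma-joined specimen IDs), read_support.  ``provenance``
    records counts into and out of the collapse step.
    """

    df: pd.DataFrame
    genome_tag: str = ""
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def per_chrom(self):
        """{chrom: (positions int64, tumor_id object array)} in sorted order."""
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            out[chrom] = (
                sub["pos"].to_numpy(dtype=np.int64),
                sub["tumor_id"].to_numpy(dtype=object),
                sub["strand"].to_numpy(dtype=object),
            )
        return out

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.tumor_id}\t"
                    f"{row.read_support}\t{row.strand}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "InsertionCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tumor_id": str, "specimens": str})
        return cls(df[CATALOG_COLUMNS])


def _sites_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        df = sites.copy()
    else:
        rows = [
            (s.chrom, s.pos, s.strand, s.tumor_id, s.specimen_id, s.read_support)
            for s in sites
        ]
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "tumor_id", "specimen_id", "read_support"]
        )
    if "read_support" not in df:
        df["read_support"] = 1
    if "specimen_id" not in df:
        df["specimen_id"] = ""
    if len(df) and df["tumor_id"].isna().any():
        raise ValueError("dedup requires a tumor ID on every site")
    return df


def dedup_sites(sites, tolerance: int = 5) -> InsertionCatalog:
    """Collapse mapped sites into per-tumor-unique insertions.

    Within one (tumor, chromosome, strand) group, positions within
    ``tolerance`` bp of each other — transitively chained — merge into one
    insertion placed at the support-weighted modal position (ties to the
    smallest position); read support is summed and specimen IDs are unioned.
    No merging ever happens across tumors.

    ``sites`` may be an iterable of :class:`~cisscout.readproc.MappedSite`
    or a DataFrame with columns chrom, pos, strand, tumor_id
    (plus optional specimen_id, read_support).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    df = _sites_frame(sites)
    n_in = len(df)
    if n_in == 0:
        cat = InsertionCatalog(pd.DataFrame(columns=CATALOG_COLUMNS))
        cat.provenance = {"sites_in": 0, "insertions_out": 0, "tolerance": tolerance}
        return cat

    out_rows = []
    for (tumor, chrom, strand), sub in df.groupby(["tumor_id", "chrom", "strand"], sort=True):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        support = sub["read_support"].to_numpy(dtype=np.int64)[order]
        specimens = sub["specimen_id"].to_numpy(dtype=object)[order]
        breaks = np.nonzero(np.diff(pos) > tolerance)[0] + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            p, s = pos[chunk], support[chunk]
            by_pos: dict[int, int] = {}
            for pi, si in zip(p, s):
                by_pos[int(pi)] = by_pos.get(int(pi), 0) + int(si)
            best = min(by_pos, key=lambda x: (-by_pos[x], x))
            specs = sorted({str(specimens[i]) for i in chunk if str(specimens[i])})
            out_rows.append((chrom, best, strand, tumor, ",".join(specs), int(s.sum())))

    out = pd.DataFrame(out_rows, columns=CATALOG_COLUMNS)
    out = out.sort_values(["chrom", "pos", "strand", "tumor_id"], kind="stable").reset_index(
        drop=True
    )
    cat = InsertionCatalog(out)
    cat.provenance = {"sites_in": n_in, "insertions_out": len(out), "tolerance": tolerance}
    return cat


def from_truth(truth: pd.DataFrame, tolerance: int = 5) -> InsertionCatalog:
    """Catalog straight from a simulated truth table (skipping read space)."""
    df = truth.rename(columns={"site_id": "read_id"})[
        ["chrom", "pos", "strand", "tumor_id", "specimen_id"]
    ].copy()
    df["read_support"] = 1
    return dedup_sites(df, tolerance=tolerance)


def catalog_stats(catalog: InsertionCatalog, genome=None) -> dict:
    """Summary counts: per-tumor totals, genome-wide total, density per Mb."""
    df = catalog.df
    per_tumor = (
        df.groupby("tumor_id").size().sort_index() if len(df) else pd.Series(dtype=int)
    )
    stats = {
        "total_insertions": int(len(df)),
        "n_tumors": int(per_tumor.size),
        "per_tumor": per_tumor.to_dict(),
        "total_read_support": int(df["read_support"].sum()) if len(df) else 0,
    }
    if genome is not None and genome.total_length > 0:
        stats["density_per_mb"] = len(df) / (genome.total_length / 1e6)
    return stats
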