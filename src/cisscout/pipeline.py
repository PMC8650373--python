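"""End-to-end screen pipeline: simulate -> process -> catalog -> call -> annotate -> filter.

A single YAML document configures every stage; the resolved configuration
and one global seed are written beside the outputs, and per-stage seeds are
derived from the global seed by fixed offsets so any stage can be rerun in
isolation.  Rerunning the same configuration reproduces byte-identical
tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import catalog as catalog_mod
from . import ciscall, filters, readproc, simgen

logger = logging.getLogger(__name__)

#: fixed per-stage seed offsets derived from the global seed
SEED_OFFSETS = {
    "genome": 1,
    "cohort": 2,
    "reads": 3,
    "scan": 4,
    "genes": 5,
    "clinical": 6,
}

ARTIFACTS = {
    "config": "config.resolved.yaml",
    "genes_gff": "genes.gff3",
    "truth": "truth_insertions.tsv",
    "truth_map": "truth_reads.tsv",
    "fastq": "reads.fastq",
    "rejections": "rejections.tsv",
    "catalog_bed": "catalog.bed",
    "catalog_tsv": "catalog.tsv",
    "thresholds": "thresholds.tsv",
    "cis_bed": "cis.bed",
    "cis_tsv": "cis.tsv",
    "candidates": "candidates.tsv",
    "filter1": "filter1.tsv",
    "log": "run.log",
}

DEFAULT_CONFIG = {
    "seed": 0,
    "genome": {"chromosomes": [["chr1", 2_000_000], ["chr2", 1_500_000]]},
    "cohort": {
        "n_tumors": 8,
        "specimens_per_tumor": 2,
        "background_insertions_per_specimen": 30,
        "cis_specs": [],
    },
    "protocol": {},
    "catalog": {"tolerance": 5},
    "scan": {"mc_iterations": 300},
    "genes": {"n_genes": 40},
    "annotate": {"max_distance": 100_000},
    "clinical": {
        "n_patients": 200,
        "censoring_rate": 0.3,
        "hazard_ratio_per_gene": {},
        "dependency_score_per_gene": {},
    },
    "filter1": {"alpha": 0.05, "dependency_threshold": -0.5},
}


@dataclass
class RunConfig:
    """One document holding every stage's parameters plus the global seed.

    The raw mapping is kept verbatim so serialization round-trips unchanged.
    """

    data: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CONFIG)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        _deep_update(merged, loaded)
        return cls(merged)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2**31 - 1)


def _deep_update(base: dict, extra: dict) -> None:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


def _cohort_spec(cfg: RunConfig) -> simgen.CohortSpec:
    c = cfg.data["cohort"]
    spikes = tuple(simgen.SpikedCIS(**s) for s in c.get("cis_specs", []))
    return simgen.CohortSpec(
        n_tumors=int(c["n_tumors"]),
        specimens_per_tumor=int(c["specimens_per_tumor"]),
        background_insertions_per_specimen=int(c["background_insertions_per_specimen"]),
        cis_specs=spikes,
        seed=cfg.stage_seed("cohort"),
    )


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage, writing intermediate artifacts to ``outdir``.

    Any stage failure aborts with the stage name in the raised error.
    Returns the run directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    stage = "setup"

    def done(name, detail=""):
        log_lines.append(f"{time.strftime('%H:%M:%S')}\t{name}\t{detail}")

    try:
        stage = "config"
        config.to_yaml(outdir / ARTIFACTS["config"])
        done(stage, f"seed={config.seed}")

        stage = "genome"
        gspec = simgen.GenomeSpec(
            chromosomes=tuple((n, int(l)) for n, l in config.data["genome"]["chromosomes"]),
            seed=config.stage_seed("genome"),
        )
        genome = simgen.make_genome(gspec)
        done(stage, f"{len(genome.names)} chromosomes, {genome.total_length} bp")

        stage = "genes"
        genes = simgen.simulate_genes(
            genome, int(config.data["genes"]["n_genes"]), seed=config.stage_seed("genes")
        )
        simgen.write_gff3(genes, outdir / ARTIFACTS["genes_gff"])
        done(stage, f"{len(genes)} gene models")

        stage = "insertions"
        truth = simgen.simulate_insertions(genome, _cohort_spec(config))
        truth.to_csv(outdir / ARTIFACTS["truth"], sep="\t", index=False)
        done(stage, f"{len(truth)} truth sites")

        stage = "reads"
        protocol = simgen.ProtocolParams(**config.data.get("protocol", {}))
        records, truth_map, dropped = simgen.simulate_reads(
            genome, truth, protocol, seed=config.stage_seed("reads")
        )
        simgen.write_fastq(records, outdir / ARTIFACTS["fastq"])
        truth_map.to_csv(outdir / ARTIFACTS["truth_map"], sep="\t", index=False)
        done(stage, f"{len(records)} reads, {len(dropped)} sites unrecoverable")

        stage = "readproc"
        reads = readproc.read_fastx(outdir / ARTIFACTS["fastq"])
        sites, rejections = readproc.process_reads(reads, genome, protocol)
        readproc.write_rejections(rejections, outdir / ARTIFACTS["rejections"])
        done(stage, f"{len(sites)} mapped, {len(rejections)} rejected")

        stage = "catalog"
        cat = catalog_mod.dedup_sites(sites, tolerance=int(config.data["catalog"]["tolerance"]))
        cat.to_bed(outdir / ARTIFACTS["catalog_bed"])
        cat.to_tsv(outdir / ARTIFACTS["catalog_tsv"])
        done(stage, f"{len(cat)} unique insertions")

        stage = "ciscall"
        scan_cfg = dict(config.data.get("scan", {}))
        scan_cfg["seed"] = config.stage_seed("scan")
        if "window_sizes" in scan_cfg:
            scan_cfg["window_sizes"] = tuple(int(w) for w in scan_cfg["window_sizes"])
        params = ciscall.ScanParams(**scan_cfg)
        thresholds = ciscall.calibrate_thresholds(len(cat), genome, params)
        thresholds.to_tsv(outdir / ARTIFACTS["thresholds"])
        calls = ciscall.call_cis(cat, genome, params, thresholds)
        ciscall.calls_to_bed(calls, outdir / ARTIFACTS["cis_bed"])
        ciscall.calls_to_frame(calls).to_csv(outdir / ARTIFACTS["cis_tsv"], sep="\t", index=False)
        done(stage, f"{len(calls)} CIS")

        stage = "annotate"
        candidates = annotate_mod.assign_genes(
            calls, genes, max_distance=int(config.data["annotate"]["max_distance"])
        )
        cand_df = annotate_mod.candidates_to_frame(candidates)
        cand_df.to_csv(outdir / ARTIFACTS["candidates"], sep="\t", index=False)
        done(stage, f"{len(candidates)} CIS-gene assignments")

        stage = "filter1"
        cand_genes = tuple(sorted(set(cand_df.loc[cand_df["gene"] != "", "gene"])))
        if cand_genes:
            clin = dict(config.data.get("clinical", {}))
            clin["genes"] = cand_genes
            clin["seed"] = config.stage_seed("clinical")
            cspec = simgen.ClinicalSimSpec(**clin)
            expr, surv, dep = simgen.simulate_clinical(cspec)
            f1 = config.data.get("filter1", {})
            outcome = filters.run_filter1(
                cand_df,
                expr,
                dep,
                alpha=float(f1.get("alpha", 0.05)),
                dependency_threshold=float(f1.get("dependency_threshold", -0.5)),
                survival=surv,
            )
        else:
            outcome = filters.run_filter1(
                pd.DataFrame(columns=["gene", "effect"]),
                pd.DataFrame(),
                pd.DataFrame(),
                survival=pd.DataFrame(columns=["time", "event"]),
            )
        outcome.to_csv(outdir / ARTIFACTS["filter1"], sep="\t", index=False)
        done(stage, f"{int(outcome['filter1_pass'].sum()) if len(outcome) else 0} genes pass")

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        (outdir / ARTIFACTS["log"]).write_text("\n".join(log_lines) + "\n")
    return outdir


def report(run_dir, top_n: int = 100) -> str:
    """Human-readable screen report cross-checked against the run artifacts."""
    run_dir = Path(run_dir)
    for key in ("catalog_tsv", "cis_tsv", "candidates"):
        if not (run_dir / ARTIFACTS[key]).exists():
            raise FileNotFoundError(f"missing artifact: {ARTIFACTS[key]}")
    cat = pd.read_csv(run_dir / ARTIFACTS["catalog_tsv"], sep="\t")
    cis = pd.read_csv(run_dir / ARTIFACTS["cis_tsv"], sep="\t")
    cand = pd.read_csv(run_dir / ARTIFACTS["candidates"], sep="\t")

    lines = [
        f"cisscout screen report — {run_dir}",
        "=" * 60,
        f"unique insertions        : {len(cat)}",
        f"tumors represented       : {cat['tumor_id'].nunique() if len(cat) else 0}",
        f"CIS called               : {len(cis)}",
        f"CIS-gene assignments     : {len(cand)}",
        "",
        f"top {top_n} candidates (by insertion frequency):",
        "rank\tcis_id\tgene\teffect\tchrom\tinterval\tinsertions",
    ]
    if len(cand):
        shown = cand.sort_values("rank").head(top_n)
        by_cis = cis.set_index("cis_id")
        for row in shown.itertuples(index=False):
            n_ins = by_cis.loc[row.cis_id, "n_insertions"] if row.cis_id in by_cis.index else ""
            lines.append(
                f"{row.rank}\t{row.cis_id}\t{row.gene or '-'}\t{row.effect}\t"
                f"{row.chrom}\t[{row.start}, {row.end})\t{n_ins}"
            )
    return "\n".join(lines) + "\n"
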