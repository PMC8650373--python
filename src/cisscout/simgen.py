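"""Synthetic-screen generator.

Everything the analysis pipeline consumes can be simulated here with exact
truth bookkeeping: a multi-chromosome genome with a restriction-site
landscape, tumor cohorts carrying uniform background insertions plus spiked
common-insertion-site (CIS) clusters, linker-mediated-PCR junction amplicons
(nested LTR primer -> genomic flank to the nearest MseI/NlaIII cut -> ligated
adaptor), synthetic gene models, and clinical expression/survival/dependency
tables with a configurable hazard association.

The emulated chemistry: tumor DNA is digested with MseI (TTAA) or NlaIII
(CATG), ligated to double-stranded adaptors, digested with EcoRV (GATATC) to
eliminate provirus-internal fragments, and amplified by two rounds of nested
PCR between primers in the proviral LTR and the adaptor.  A sequencing read
therefore starts with the nested LTR primer, runs through the host flank up
to the restriction cut, and ends in the reverse complement of the nested
adaptor primer.

All randomness flows through :class:`numpy.random.Generator` seeded from the
spec objects, so identical specs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import find_motif_positions, random_dna, revcomp, validate_dna

logger = logging.getLogger(__name__)

#: MseI and NlaIII recognition sequences.
DEFAULT_MOTIFS = ("TTAA", "CATG")

TRUTH_COLUMNS = ["site_id", "chrom", "pos", "strand", "tumor_id", "specimen_id", "label"]
TRUTH_MAP_COLUMNS = ["read_id", "chrom", "pos", "strand", "tumor_id", "specimen_id", "label"]


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for a synthetic genome.

    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    restriction_motifs
        Recognition sequences indexed during generation (defaults: MseI TTAA,
        NlaIII CATG).
    seed
        Seed for the i.i.d. uniform A/C/G/T sequence.
    sequence_overrides
        Optional literal sequences keyed by chromosome name (fixture hook);
        the stated length must match.
    """

    chromosomes: tuple
    restriction_motifs: tuple = DEFAULT_MOTIFS
    seed: int = 0
    sequence_overrides: Mapping[str, str] | None = None

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        for motif in self.restriction_motifs:
            validate_dna(motif, "restriction motif")
        if self.sequence_overrides:
            lengths = dict(self.chromosomes)
            for name, seq in self.sequence_overrides.items():
                if name not in lengths:
                    raise ValueError(f"override for unknown chromosome {name!r}")
                if len(seq) != lengths[name]:
                    raise ValueError(
                        f"override for {name!r} has length {len(seq)}, spec says {lengths[name]}"
                    )
                validate_dna(seq, f"override sequence for {name!r}")


class Genome:
    """Synthetic genome: ordered chromosomes, optional sequence, motif index.

    ``motif_index[motif][chrom]`` is a sorted int64 array of every 0-based
    occurrence of ``motif`` on ``chrom`` (overlaps included).  A coordinate-only
    genome (no sequence, no motif index) can be built with
    :meth:`from_chrom_sizes` for insertion-level statistics that never touch
    sequence.
    """

    def __init__(self, names, lengths, sequences=None, motif_index=None, spec=None):
        self.names: list[str] = list(names)
        self.lengths: dict[str, int] = dict(lengths)
        self.sequences: dict[str, str] | None = sequences
        self.motif_index: dict[str, dict[str, np.ndarray]] | None = motif_index
        self.spec = spec
        self.offsets = np.concatenate(
            [[0], np.cumsum([self.lengths[n] for n in self.names])]
        ).astype(np.int64)

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    @property
    def has_sequence(self) -> bool:
        return self.sequences is not None

    @classmethod
    def from_chrom_sizes(cls, sizes: Mapping[str, int]) -> "Genome":
        """Coordinate-only genome (lengths, no sequence)."""
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        return cls(list(sizes), sizes)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if not self.has_sequence:
            raise ValueError("genome carries no sequence")
        return self.sequences[chrom][start:end]

    def global_to_chrom(self, positions: np.ndarray):
        """Map global 0-based coordinates to (chrom_index, within-chrom pos)."""
        idx = np.searchsorted(self.offsets, positions, side="right") - 1
        return idx, positions - self.offsets[idx]


def make_genome(spec: GenomeSpec) -> Genome:
    """Generate a genome from a spec: sequence plus restriction-motif index.

    Deterministic for a fixed seed.  Motif occurrences are recoverable by
    re-scanning the emitted sequence (the index is literally that scan).
    """
    rng = np.random.default_rng(spec.seed)
    overrides = dict(spec.sequence_overrides or {})
    sequences, motif_index = {}, {m: {} for m in spec.restriction_motifs}
    for name, length in spec.chromosomes:
        seq = overrides.get(name) or random_dna(rng, length)
        sequences[name] = seq
        for motif in spec.restriction_motifs:
            motif_index[motif][name] = find_motif_positions(seq, motif)
    return Genome(
        [n for n, _ in spec.chromosomes],
        dict(spec.chromosomes),
        sequences,
        motif_index,
        spec,
    )


# ---------------------------------------------------------------------------
# cohorts and insertions


@dataclass(frozen=True)
class SpikedCIS:
    """A truth CIS cluster injected into a simulated cohort.

    ``n_insertions`` sites are placed within ``width`` bp centred on
    ``center``; no tumor contributes more than ``tumor_multiplicity`` of them;
    ``strand_bias`` is the probability a site is on the plus strand.
    """

    chromosome: str
    center: int
    width: int
    n_insertions: int
    tumor_multiplicity: int = 1
    strand_bias: float = 0.5

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("SpikedCIS width must be positive")
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")
        if self.tumor_multiplicity < 1:
            raise ValueError("tumor_multiplicity must be >= 1")
        if not 0.0 <= self.strand_bias <= 1.0:
            raise ValueError("strand_bias must lie in [0, 1]")

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.center + self.width // 2


@dataclass(frozen=True)
class CohortSpec:
    """A simulated tumor cohort.

    Defaults reproduce the screen's scale: 21 B-lineage tumor-bearing mice,
    8 specimens per mouse (168 specimens), and 268 background insertions per
    specimen for ~45,000 integration events genome-wide.
    """

    n_tumors: int = 21
    specimens_per_tumor: int = 8
    background_insertions_per_specimen: int = 268
    cis_specs: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tumors, self.specimens_per_tumor) < 0:
            raise ValueError("counts must be >= 0")
        if self.background_insertions_per_specimen < 0:
            raise ValueError("background_insertions_per_specimen must be >= 0")

    @property
    def n_specimens(self) -> int:
        return self.n_tumors * self.specimens_per_tumor

    @property
    def total_insertions(self) -> int:
        return self.n_specimens * self.background_insertions_per_specimen + sum(
            c.n_insertions for c in self.cis_specs
        )


def simulate_insertions(genome: Genome, cohort: CohortSpec) -> pd.DataFrame:
    """Place background and spiked insertions; return the truth catalog.

    Background sites are uniform over the genome.  Spiked sites honour the
    :class:`SpikedCIS` geometry and per-tumor multiplicity.  The returned
    DataFrame has columns ``site_id, chrom, pos, strand, tumor_id,
    specimen_id, label`` with label ``background`` or ``cis<i>``; the row
    count equals background + spiked totals exactly.
    """
    rng = np.random.default_rng(cohort.seed)
    tumors = [f"T{i + 1:02d}" for i in range(cohort.n_tumors)]
    specimens = {
        t: [f"{t}S{j + 1}" for j in range(cohort.specimens_per_tumor)] for t in tumors
    }
    rows: list[tuple] = []

    n_bg = cohort.background_insertions_per_specimen
    if n_bg and cohort.n_specimens:
        flat_specimens = [s for t in tumors for s in specimens[t]]
        total = n_bg * len(flat_specimens)
        gpos = rng.integers(0, genome.total_length, size=total)
        cidx, pos = genome.global_to_chrom(gpos)
        strands = np.where(rng.random(total) < 0.5, "+", "-")
        k = 0
        for spec_name in flat_specimens:
            tumor = spec_name.split("S")[0]
            for _ in range(n_bg):
                rows.append(
                    (genome.names[cidx[k]], int(pos[k]), strands[k], tumor, spec_name, "background")
                )
                k += 1

    for ci, cis in enumerate(cohort.cis_specs):
        if cis.chromosome not in genome.lengths:
            raise ValueError(f"SpikedCIS on unknown chromosome {cis.chromosome!r}")
        chrom_len = genome.lengths[cis.chromosome]
        if cis.width > chrom_len or cis.start < 0 or cis.end >= chrom_len:
            raise ValueError(
                f"SpikedCIS [{cis.start}, {cis.end}] exceeds chromosome "
                f"{cis.chromosome!r} of length {chrom_len}"
            )
        if cis.n_insertions > cohort.n_tumors * cis.tumor_multiplicity:
            raise ValueError(
                "SpikedCIS asks for more insertions than n_tumors * tumor_multiplicity"
            )
        span = cis.end - cis.start + 1
        if span >= cis.n_insertions:
            pos = np.sort(
                rng.choice(np.arange(cis.start, cis.end + 1), size=cis.n_insertions, replace=False)
            )
        else:
            pos = np.sort(rng.integers(cis.start, cis.end + 1, size=cis.n_insertions))
        order = rng.permutation(cohort.n_tumors)
        slots = [tumors[i] for i in order for _ in range(cis.tumor_multiplicity)]
        strands = np.where(rng.random(cis.n_insertions) < cis.strand_bias, "+", "-")
        for j in range(cis.n_insertions):
            tumor = slots[j]
            spec_name = specimens[tumor][int(rng.integers(0, cohort.specimens_per_tumor))]
            rows.append((cis.chromosome, int(pos[j]), strands[j], tumor, spec_name, f"cis{ci}"))

    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS[1:])
    df.insert(0, "site_id", [f"ins{i:06d}" for i in range(len(df))])
    assert len(df) == cohort.total_insertions
    return df


# ---------------------------------------------------------------------------
# amplicon reads


@dataclass(frozen=True)
class ProtocolParams:
    """Linker-mediated-PCR protocol constants.

    Primer and linker defaults are the published protocol sequences; a read
    is ``ltr_nested_primer + host flank + revcomp(adaptor_nested_primer)``
    truncated to ``read_length``, with per-base substitution errors at
    ``error_rate``.
    """

    ltr_nested_primer: str = "CCAAACCTACAGGTGGGGTCTTTC"
    adaptor_nested_primer: str = "AGGGCTCCGCTTAAGGGAC"
    nlaiii_linker_top: str = "GTAATACGACTCACTATAGGGCTCCGCTTAAGGGACCATG"
    msei_linker_top: str = "GTAATACGACTCACTATAGGGCTCCGCTTAAGGGAC"
    eco_rv_site: str = "GATATC"
    read_length: int = 150
    error_rate: float = 0.002
    min_flank: int = 20

    def __post_init__(self):
        for name in (
            "ltr_nested_primer",
            "adaptor_nested_primer",
            "nlaiii_linker_top",
            "msei_linker_top",
            "eco_rv_site",
        ):
            validate_dna(getattr(self, name), name)
        if self.read_length < len(self.ltr_nested_primer) + self.min_flank:
            raise ValueError("read_length must cover the LTR primer plus a minimum flank")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


def _nearest_cut(genome: Genome, chrom: str, pos: int, strand: str, max_flank: int):
    """Closest restriction cut on the fragment side of a junction.

    Returns ``(motif, fragment_start, fragment_end)`` for the host fragment
    between the junction and the cut (motif included), or None when no motif
    lies within ``max_flank``.
    """
    best = None
    for motif, per_chrom in genome.motif_index.items():
        occ = per_chrom[chrom]
        if strand == "+":
            i = np.searchsorted(occ, pos, side="left")
            if i == len(occ):
                continue
            frag = (pos, int(occ[i]) + len(motif))
        else:
            # motif must lie fully within [.., pos]
            i = np.searchsorted(occ, pos - len(motif) + 1, side="right") - 1
            if i < 0:
                continue
            frag = (int(occ[i]), pos + 1)
        length = frag[1] - frag[0]
        if length > max_flank:
            continue
        if best is None or length < best[2] - best[1]:
            best = (motif, frag[0], frag[1])
    return best


def simulate_reads(
    genome: Genome,
    truth: pd.DataFrame,
    protocol: ProtocolParams = ProtocolParams(),
    seed: int = 0,
    max_flank: int = 2000,
    pcr_duplicates: int = 1,
):
    """Build junction amplicon reads for every recoverable truth site.

    A site is unrecoverable (dropped with a logged reason) when no MseI/NlaIII
    cut lies within ``max_flank`` of the junction on the fragment side, when
    the flank would be empty, or when the host fragment contains an EcoRV site
    (EcoRV digestion precedes PCR and cuts such fragments between LTR and
    adaptor).  Provirus-internal fragments — EcoRV's actual target — are never
    emitted at all.

    Returns ``(records, truth_map, dropped)``: FASTQ-ready
    :class:`~Bio.SeqRecord.SeqRecord` objects with constant Phred-40 quality,
    a read_id -> truth-site table, and a list of ``(site_id, reason)`` pairs.
    """
    if not genome.has_sequence:
        raise ValueError("read simulation needs a genome with sequence")
    rng = np.random.default_rng(seed)
    ltr = protocol.ltr_nested_primer
    adaptor_rc = revcomp(protocol.adaptor_nested_primer)
    records, map_rows, dropped = [], [], []

    for row in truth.itertuples(index=False):
        cut = _nearest_cut(genome, row.chrom, row.pos, row.strand, max_flank)
        if cut is None:
            dropped.append((row.site_id, "no_restriction_site"))
            continue
        _, frag_start, frag_end = cut
        frag = genome.fetch(row.chrom, frag_start, frag_end)
        if not frag:
            dropped.append((row.site_id, "zero_flank"))
            continue
        if protocol.eco_rv_site in frag:
            dropped.append((row.site_id, "ecorv_cut"))
            continue
        flank = frag if row.strand == "+" else revcomp(frag)
        read = (ltr + flank + adaptor_rc)[: protocol.read_length]
        for dup in range(pcr_duplicates):
            read_id = f"{row.tumor_id}|{row.specimen_id}|{row.site_id}"
            if pcr_duplicates > 1:
                read_id += f"|d{dup}"
            seq = read
            if protocol.error_rate > 0:
                seq = _substitute(rng, seq, protocol.error_rate)
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
            map_rows.append(
                (read_id, row.chrom, row.pos, row.strand, row.tumor_id, row.specimen_id, row.label)
            )

    for site_id, reason in dropped:
        logger.warning("site %s emitted no read (%s)", site_id, reason)
    truth_map = pd.DataFrame(map_rows, columns=TRUTH_MAP_COLUMNS)
    return records, truth_map, dropped


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit) == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# synthetic gene models


def simulate_genes(
    genome: Genome,
    n_genes: int,
    seed: int = 0,
    mean_length: int = 30_000,
    sigma: float = 0.5,
):
    """Non-overlapping synthetic gene models, lognormal lengths around 30 kb
    (the average mouse transcriptional unit), random strands, 1-5 exons.
    Returns a list of :class:`cisscout.annotate.GeneModel` sorted by position.
    """
    from .annotate import GeneModel

    rng = np.random.default_rng(seed)
    weights = np.array([genome.lengths[n] for n in genome.names], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.names}
    genes, attempts = [], 0
    while len(genes) < n_genes and attempts < 50 * n_genes:
        attempts += 1
        chrom = genome.names[rng.choice(len(genome.names), p=weights)]
        length = int(np.clip(rng.lognormal(np.log(mean_length), sigma), 2_000, 200_000))
        if length >= genome.lengths[chrom]:
            continue
        start = int(rng.integers(0, genome.lengths[chrom] - length))
        end = start + length
        if any(s < end and start < e for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        exons = tuple(
            (start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
            for i in range(n_exons)
        )
        genes.append(
            GeneModel(
                gene_id=f"G{len(genes) + 1:04d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
            )
        )
    chrom_rank = {n: i for i, n in enumerate(genome.names)}
    genes.sort(key=lambda g: (chrom_rank[g.chrom], g.start))
    return genes


def write_gff3(genes, path) -> None:
    """Write gene models as GFF3 (gene + exon features, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcisscout\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tcisscout\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{j + 1};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# clinical tables


@dataclass(frozen=True)
class ClinicalSimSpec:
    """Emulated patient expression/survival and cell-line dependency tables.

    Survival is exponential: a patient's hazard is ``baseline_hazard``
    multiplied by ``hazard_ratio_per_gene[g]`` for every gene ``g`` in whose
    top expression quartile the patient falls.  Censoring is independent
    exponential, tuned so a baseline-hazard patient is censored with
    probability ``censoring_rate``.  Units are months.
    """

    n_patients: int = 776
    genes: tuple = ("GENE1",)
    hazard_ratio_per_gene: Mapping[str, float] = field(default_factory=dict)
    dependency_score_per_gene: Mapping[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.3
    seed: int = 0
    n_cell_lines: int = 20
    baseline_hazard: float = 0.02
    dependency_noise_sd: float = 0.1

    def __post_init__(self):
        if self.n_patients < 8:
            raise ValueError("n_patients must be >= 8 (quartiles undefined below that)")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        for g, hr in self.hazard_ratio_per_gene.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio for {g} must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")


def simulate_clinical(spec: ClinicalSimSpec):
    """Return ``(expression, survival, dependency)`` DataFrames.

    expression: patients x genes, standard normal.
    survival:   ``patient_id, time, event`` (event 1 = death).
    dependency: genes x cell lines, configured score plus Gaussian noise
    (more negative = more essential).
    """
    from .filters import quartile_split  # same quartile rule the filter applies

    rng = np.random.default_rng(spec.seed)
    patients = [f"P{i + 1:04d}" for i in range(spec.n_patients)]
    expr = pd.DataFrame(
        rng.standard_normal((spec.n_patients, len(spec.genes))),
        index=pd.Index(patients, name="patient_id"),
        columns=list(spec.genes),
    )

    log_hazard = np.full(spec.n_patients, np.log(spec.baseline_hazard))
    for gene in spec.genes:
        hr = spec.hazard_ratio_per_gene.get(gene, 1.0)
        if hr == 1.0:
            continue
        top, _ = quartile_split(expr, gene)
        log_hazard[expr.index.isin(top)] += np.log(hr)
    hazard = np.exp(log_hazard)
    times = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        lam_c = spec.baseline_hazard * spec.censoring_rate / (1 - spec.censoring_rate)
        censor = rng.exponential(1.0 / lam_c, size=spec.n_patients)
        event = (times <= censor).astype(int)
        times = np.minimum(times, censor)
    else:
        event = np.ones(spec.n_patients, dtype=int)
    survival = pd.DataFrame(
        {"patient_id": patients, "time": times, "event": event}
    ).set_index("patient_id")

    lines = [f"CL{j + 1:02d}" for j in range(spec.n_cell_lines)]
    dep = pd.DataFrame(
        {
            line: [
                spec.dependency_score_per_gene.get(g, 0.0)
                + rng.normal(0.0, spec.dependency_noise_sd)
                for g in spec.genes
            ]
            for line in lines
        },
        index=pd.Index(list(spec.genes), name="gene"),
    )
    return expr, survival, dep


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
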