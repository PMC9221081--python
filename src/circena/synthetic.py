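"""Synthetic data with planted ground truth.

Generates the inputs the pipeline consumes — a small multi-gene genome
with canonical GT-AG introns, reads a fraction of which span planted
back-splice junctions, two-group negative-binomial count matrices with
planted fold changes, and circRNA/3'UTR/miRNA sequences sharing planted
seed sites — together with a :class:`SyntheticTruth` record that every
downstream stage is scored against.  Every generator is a pure function
of its arguments including ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bsj import make_circ_id
from .io import CountMatrix, ExonAnnotation, GenomeSequence, ReadRecord, revcomp

__all__ = [
    "PlantedJunction",
    "SyntheticTruth",
    "NBCountModel",
    "simulate_genome",
    "choose_planted_junctions",
    "simulate_reads",
    "simulate_counts",
    "plant_cerna_triad",
    "simulate_dataset",
    "SyntheticDataset",
]

_BASES = np.array(list("ACGT"))

# Canonical splice motifs planted at every intron so PWM estimation from the
# annotation has signal: exon|GTAAGT ... polypyrimidine-CAG|exon.
_DONOR_EXON_END = "CAG"       # last 3 exonic nt before the donor
_DONOR_INTRON_START = "GTAAGT"
_ACCEPTOR_EXON_START = "G"    # first exonic nt after the acceptor
_ACCEPTOR_TAIL_LEN = 20       # intronic nt forming the acceptor window
_MIN_INTRON_LEN = len(_DONOR_INTRON_START) + _ACCEPTOR_TAIL_LEN + 2


@dataclass(frozen=True)
class PlantedJunction:
    """Ground-truth back-splice junction (genomic low/high boundaries)."""

    chrom: str
    strand: str
    acceptor_pos: int  # genomic low boundary, 1-based
    donor_pos: int     # genomic high boundary, 1-based
    n_supporting_reads: int

    def __post_init__(self) -> None:
        if self.donor_pos <= self.acceptor_pos:
            raise ValueError("donor_pos must exceed acceptor_pos")

    @property
    def circ_id(self) -> str:
        return make_circ_id(self.chrom, self.donor_pos, self.acceptor_pos)


@dataclass
class SyntheticTruth:
    """Planted ground truth for scoring every pipeline stage."""

    planted_junctions: list[PlantedJunction] = field(default_factory=list)
    planted_de: dict[str, float] = field(default_factory=dict)
    planted_triad: tuple[str, str, str, dict[str, list[int]]] | None = None


@dataclass
class NBCountModel:
    """Negative-binomial count model: mean = s_j * q_i * 2^(lfc_i * group_j),
    variance = mean + alpha_i * mean^2."""

    feature_ids: list[str]
    sample_ids: list[str]
    base_mean: np.ndarray        # q_i > 0
    size_factors: np.ndarray     # s_j > 0
    dispersion: np.ndarray       # alpha_i >= 0
    group: np.ndarray            # 0/1 per sample
    log2_fc: np.ndarray          # lfc_i
    group_names: tuple[str, str] = ("control", "glaucoma")

    def __post_init__(self) -> None:
        self.base_mean = np.asarray(self.base_mean, float)
        self.size_factors = np.asarray(self.size_factors, float)
        self.dispersion = np.asarray(self.dispersion, float)
        self.group = np.asarray(self.group, int)
        self.log2_fc = np.asarray(self.log2_fc, float)
        if np.any(self.base_mean <= 0) or np.any(self.size_factors <= 0):
            raise ValueError("base means and size factors must be positive")
        if np.any(self.dispersion < 0):
            raise ValueError("dispersion alpha must be >= 0")
        for name, arr, n in (
            ("base_mean", self.base_mean, len(self.feature_ids)),
            ("dispersion", self.dispersion, len(self.feature_ids)),
            ("log2_fc", self.log2_fc, len(self.feature_ids)),
            ("size_factors", self.size_factors, len(self.sample_ids)),
            ("group", self.group, len(self.sample_ids)),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has wrong length")
        for g in (0, 1):
            if np.sum(self.group == g) < 2:
                raise ValueError("need >= 2 samples per group")

    def mean_matrix(self) -> np.ndarray:
        return (
            self.size_factors[None, :]
            * self.base_mean[:, None]
            * 2.0 ** (self.log2_fc[:, None] * self.group[None, :])
        )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_pyrimidines(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(["C", "T"])[rng.integers(0, 2, size=n)])


# ---------------------------------------------------------------------------
# Genome and annotation


def simulate_genome(
    n_genes: int = 20,
    exons_per_gene: int = 3,
    exon_len_range: tuple[int, int] = (150, 250),
    intron_len_range: tuple[int, int] = (80, 150),
    rng_seed: int = 0,
    intergenic_len_range: tuple[int, int] = (200, 400),
    chrom_name: str = "chr1",
    both_strands: bool = True,
) -> tuple[list[GenomeSequence], list[ExonAnnotation]]:
    """A single-chromosome genome of non-overlapping multi-exon genes.

    Every intron begins with GTAAGT and ends with a pyrimidine tract and
    CAG on the annotated strand, so the first two intronic bases are GT
    and the last two AG (canonical sites give the splice scorer signal).
    """
    for lo, hi in (exon_len_range, intron_len_range, intergenic_len_range):
        if lo <= 0 or hi < lo:
            raise ValueError("length ranges must be positive with lo <= hi")
    if exons_per_gene < 1 or n_genes < 1:
        raise ValueError("need at least one gene with one exon")
    if intron_len_range[0] < _MIN_INTRON_LEN:
        raise ValueError(f"introns must be >= {_MIN_INTRON_LEN} nt for splice motifs")
    rng = np.random.default_rng(rng_seed)
    chrom_parts: list[str] = []
    annotations: list[ExonAnnotation] = []
    cursor = 0  # 0-based length so far

    for g in range(n_genes):
        chrom_parts.append(_random_dna(rng, int(rng.integers(*_incl(intergenic_len_range)))))
        cursor = sum(len(p) for p in chrom_parts)
        # Build the gene in transcript orientation, recording exon offsets.
        pieces: list[str] = []
        exon_offsets: list[tuple[int, int]] = []  # 0-based half-open within gene
        pos = 0
        for e in range(exons_per_gene):
            exon_len = int(rng.integers(*_incl(exon_len_range)))
            exon = _random_dna(rng, exon_len)
            if e < exons_per_gene - 1:  # donor side consensus at exon end
                exon = exon[: -len(_DONOR_EXON_END)] + _DONOR_EXON_END
            if e > 0:  # acceptor side consensus at exon start
                exon = _ACCEPTOR_EXON_START + exon[len(_ACCEPTOR_EXON_START) :]
            pieces.append(exon)
            exon_offsets.append((pos, pos + exon_len))
            pos += exon_len
            if e < exons_per_gene - 1:
                intron_len = int(rng.integers(*_incl(intron_len_range)))
                middle = _random_dna(
                    rng, intron_len - len(_DONOR_INTRON_START) - _ACCEPTOR_TAIL_LEN
                )
                tail = _random_pyrimidines(rng, _ACCEPTOR_TAIL_LEN - 3) + "CAG"
                pieces.append(_DONOR_INTRON_START + middle + tail)
                pos += intron_len
        gene_seq = "".join(pieces)
        strand = "+" if (not both_strands or rng.integers(0, 2) == 0) else "-"
        gene_start0 = cursor  # 0-based start of gene on the chromosome
        if strand == "+":
            chrom_parts.append(gene_seq)
            exons = tuple(
                (gene_start0 + s + 1, gene_start0 + e) for s, e in exon_offsets
            )
        else:
            chrom_parts.append(revcomp(gene_seq))
            L = len(gene_seq)
            exons = tuple(
                sorted((gene_start0 + L - e + 1, gene_start0 + L - s) for s, e in exon_offsets)
            )
        annotations.append(
            ExonAnnotation(
                gene_id=f"gene{g + 1}",
                transcript_id=f"gene{g + 1}.t1",
                chrom=chrom_name,
                strand=strand,
                exons=exons,
            )
        )
    chrom_parts.append(_random_dna(rng, int(rng.integers(*_incl(intergenic_len_range)))))
    genome = [GenomeSequence(chrom_name, "".join(chrom_parts))]
    return genome, annotations


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def choose_planted_junctions(
    annotations: Sequence[ExonAnnotation],
    n_junctions: int,
    support_range: tuple[int, int] = (3, 6),
    rng_seed: int = 0,
) -> list[PlantedJunction]:
    """Plant single-exon circles on the middle exon of distinct genes.

    Both circle boundaries sit on annotated internal exon edges, so the
    back-splice donor and acceptor reuse the gene's canonical splice
    motifs.
    """
    eligible = [a for a in annotations if len(a.exons) >= 3]
    if n_junctions > len(eligible):
        raise ValueError(
            f"cannot plant {n_junctions} junctions on {len(eligible)} genes "
            "with >= 3 exons"
        )
    rng = np.random.default_rng(rng_seed)
    chosen = sorted(rng.choice(len(eligible), size=n_junctions, replace=False))
    junctions = []
    for idx in chosen:
        ann = eligible[int(idx)]
        mid = len(ann.exons) // 2
        start, end = ann.exons[mid]
        junctions.append(
            PlantedJunction(
                chrom=ann.chrom,
                strand=ann.strand,
                acceptor_pos=start,
                donor_pos=end,
                n_supporting_reads=int(rng.integers(*_incl(support_range))),
            )
        )
    return junctions


# ---------------------------------------------------------------------------
# Reads


def _circle_sequence_for(
    junction: PlantedJunction,
    annotations: Sequence[ExonAnnotation],
    genome_map: dict[str, GenomeSequence],
) -> str:
    chrom = genome_map[junction.chrom]
    for ann in annotations:
        if ann.chrom != junction.chrom or ann.strand != junction.strand:
            continue
        inside = [
            (s, e)
            for s, e in ann.exons
            if s >= junction.acceptor_pos and e <= junction.donor_pos
        ]
        if inside and inside[0][0] == junction.acceptor_pos and inside[-1][1] == junction.donor_pos:
            seq = "".join(chrom.slice1(s, e) for s, e in inside)
            return revcomp(seq) if junction.strand == "-" else seq
    raise ValueError(
        f"planted junction {junction.circ_id} does not lie on annotated exon boundaries"
    )


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < error_rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(
    genome: Sequence[GenomeSequence],
    annotations: Sequence[ExonAnnotation],
    truth: SyntheticTruth,
    n_linear: int = 2000,
    read_len: int = 100,
    error_rate: float = 0.0,
    rng_seed: int = 0,
    min_overhang: int = 6,
    junction_overhang: int = 20,
) -> list[ReadRecord]:
    """Linear transcript reads plus planted back-splice junction reads.

    Linear reads are substrings of spliced transcripts; back-splice
    reads are substrings of each planted circle's junction sequence
    (circle 3' tail + 5' head), positioned with both overhangs at least
    ``junction_overhang`` nt (default 20): long enough for a seed-based
    split aligner to see both segments, and longer than the
    micro-homology a canonical junction shares with its linear
    neighbourhood, which would otherwise make short-overhang reads
    indistinguishable from linear ones.  ``min_overhang`` (the
    quantification floor) only bounds the pseudo-reference flank here.
    Per-junction read counts equal the truth's ``n_supporting_reads``.
    Reads are reverse-complemented with probability 1/2; substitution
    errors are injected at ``error_rate``.
    """
    if read_len < 2 * min_overhang:
        raise ValueError("read_len must be at least twice min_overhang")
    if read_len < 2 * junction_overhang:
        raise ValueError("read_len must be at least twice junction_overhang")
    if junction_overhang < min_overhang:
        raise ValueError("junction_overhang must be >= min_overhang")
    rng = np.random.default_rng(rng_seed)
    genome_map = {g.chrom_name: g for g in genome}
    transcripts = [
        (ann, ann.spliced_sequence(genome_map))
        for ann in annotations
        if sum(e - s + 1 for s, e in ann.exons) >= read_len
    ]
    if not transcripts and n_linear > 0:
        raise ValueError("no transcript long enough for the requested read length")
    reads: list[ReadRecord] = []
    for i in range(n_linear):
        ann, seq = transcripts[rng.integers(0, len(transcripts))]
        start = int(rng.integers(0, len(seq) - read_len + 1))
        frag = seq[start : start + read_len]
        if rng.integers(0, 2):
            frag = revcomp(frag)
        reads.append(
            ReadRecord(f"lin{i}_{ann.transcript_id}", _inject_errors(frag, error_rate, rng))
        )
    for j, junction in enumerate(truth.planted_junctions):
        circle = _circle_sequence_for(junction, annotations, genome_map)
        flank = read_len - min_overhang
        if len(circle) < read_len:
            raise ValueError(
                f"planted circle {junction.circ_id} shorter than the read length"
            )
        pseudo = circle[-flank:] + circle[:flank]
        # read start offsets keeping both overhangs >= junction_overhang
        lo = flank - (read_len - junction_overhang)
        hi = flank - junction_overhang
        for r in range(junction.n_supporting_reads):
            start = int(rng.integers(lo, hi + 1))
            frag = pseudo[start : start + read_len]
            if rng.integers(0, 2):
                frag = revcomp(frag)
            reads.append(
                ReadRecord(f"bsj{j}_{r}_{junction.circ_id}",
                           _inject_errors(frag, error_rate, rng))
            )
    return reads


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    model: NBCountModel, rng_seed: int = 0
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix from the NB model; truth records planted LFCs."""
    rng = np.random.default_rng(rng_seed)
    mean = model.mean_matrix()
    alpha = model.dispersion[:, None]
    counts = np.empty(mean.shape, dtype=np.int64)
    poisson_rows = model.dispersion == 0
    counts[poisson_rows] = rng.poisson(mean[poisson_rows])
    nb_rows = ~poisson_rows
    if np.any(nb_rows):
        r = 1.0 / alpha[nb_rows]
        p = r / (r + mean[nb_rows])
        counts[nb_rows] = rng.negative_binomial(r, p)
    groups = {
        s: model.group_names[g] for s, g in zip(model.sample_ids, model.group)
    }
    matrix = CountMatrix(list(model.feature_ids), list(model.sample_ids), counts, groups)
    truth = SyntheticTruth(
        planted_de={
            f: float(l) for f, l in zip(model.feature_ids, model.log2_fc) if l != 0
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# ceRNA triad sequences


def _seed_core(mirna_rna: str) -> str:
    """DNA reverse complement of miRNA positions 2-7 (the 6mer core site)."""
    seed = mirna_rna[1:7].replace("U", "T")
    return revcomp(seed)


def _site_7mer_m8(mirna_rna: str) -> str:
    """DNA reverse complement of miRNA positions 2-8 (a 7mer-m8 site)."""
    seed = mirna_rna[1:8].replace("U", "T")
    return revcomp(seed)


_SITE_SPACER = 4  # target nt bridging seed and 3'-supplementary pairing


def _site_cassette(mirna_rna: str, rng: np.random.Generator) -> str:
    """Target-side insert for one planted site: 3'-supplementary pairing
    (miRNA 13-18) upstream of the 7mer-m8 seed site, bridged by a short
    spacer — the canonical architecture of a functional site, and enough
    duplex support for the site to clear the default score threshold."""
    supp = revcomp(mirna_rna[12:18].replace("U", "T"))
    spacer = _random_dna(rng, _SITE_SPACER)
    return supp + spacer + _site_7mer_m8(mirna_rna)


def _count_core_matches(seq: str, core: str) -> int:
    count, start = 0, 0
    while True:
        i = seq.find(core, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _background_without_core(
    rng: np.random.Generator, n: int, core: str, max_tries: int = 200
) -> str:
    for _ in range(max_tries):
        seq = _random_dna(rng, n)
        if _count_core_matches(seq, core) == 0:
            return seq
    raise RuntimeError("could not sample background free of seed matches")


def _embed_sites(
    rng: np.random.Generator,
    length: int,
    site: str,
    core: str,
    positions: list[int],
    max_tries: int = 200,
) -> str:
    """Background sequence with the site cassette at the given 1-based
    positions and no seed-core match anywhere outside the planted seeds."""
    for _ in range(max_tries):
        seq = list(_background_without_core(rng, length, core))
        for pos in positions:
            seq[pos - 1 : pos - 1 + len(site)] = site
        out = "".join(seq)
        if _count_core_matches(out, core) == len(positions):
            return out
    raise RuntimeError("could not embed seed sites without spurious matches")


def plant_cerna_triad(
    circ_seq_len: int = 400,
    utr_len: int = 600,
    mirna_len: int = 22,
    n_shared_sites: int = 2,
    rng_seed: int = 0,
) -> tuple[str, str, str, SyntheticTruth]:
    """A circRNA sequence, an mRNA 3'UTR and a miRNA sharing seed sites.

    Exact 7mer-m8 sites for the miRNA are embedded at recorded positions
    in BOTH the circ and UTR sequences; the background is rejection-
    sampled so it contains no additional seed-core matches.  Returns
    (circ_dna, utr_dna, mirna_rna, truth) with site positions recorded
    in the truth's planted triad.
    """
    rng = np.random.default_rng(rng_seed)
    mirna = "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=mirna_len)])
    cassette, core = _site_cassette(mirna, rng), _seed_core(mirna)
    site_offset = len(cassette) - 7  # the seed 7-mer sits at the cassette end
    spacing = mirna_len + 12  # leave room for the 3'-supplementary window

    def pick_positions(length: int) -> list[int]:
        lo, hi = spacing, length - len(cassette)
        needed = n_shared_sites * spacing
        if n_shared_sites and hi - lo < needed:
            raise ValueError(
                f"cannot pack {n_shared_sites} sites into {length} nt"
            )
        positions: list[int] = []
        while len(positions) < n_shared_sites:
            p = int(rng.integers(lo, hi + 1))
            if all(abs(p - q) >= spacing for q in positions):
                positions.append(p)
        return sorted(positions)

    circ_pos = pick_positions(circ_seq_len)
    utr_pos = pick_positions(utr_len)
    circ = _embed_sites(rng, circ_seq_len, cassette, core, circ_pos)
    utr = _embed_sites(rng, utr_len, cassette, core, utr_pos)
    truth = SyntheticTruth(
        planted_triad=(
            "circ_planted",
            "mir_planted",
            "mrna_planted",
            {
                "circ": [p + site_offset for p in circ_pos],
                "mrna": [p + site_offset for p in utr_pos],
            },
        )
    )
    return circ, utr, mirna, truth


# ---------------------------------------------------------------------------
# Full dataset with a planted triad


@dataclass
class SyntheticDataset:
    """Everything the end-to-end pipeline consumes, plus ground truth."""

    genome: list[GenomeSequence]
    annotations: list[ExonAnnotation]
    reads: list[ReadRecord]
    mirnas: dict[str, str]          # id -> RNA sequence 5'->3'
    mrna_seqs: dict[str, str]       # gene id -> 3'UTR (last exon) DNA
    circ_counts: CountMatrix
    mrna_counts: CountMatrix
    truth: SyntheticTruth


def _oriented_exon_seq(chrom_seq: str, exon: tuple[int, int], strand: str) -> str:
    s, e = exon
    seq = chrom_seq[s - 1 : e]
    return revcomp(seq) if strand == "-" else seq


def _utr_exon(ann: ExonAnnotation) -> tuple[int, int]:
    """Genomic interval of the transcript's 3'-most exon (the 3'UTR proxy)."""
    return ann.exons[-1] if ann.strand == "+" else ann.exons[0]


def simulate_dataset(
    n_genes: int = 24,
    n_circ: int = 12,
    n_mirnas: int = 8,
    n_linear_reads: int = 1500,
    read_len: int = 100,
    error_rate: float = 0.0,
    samples_per_group: int = 3,
    planted_lfc: float = -1.5,
    rng_seed: int = 0,
) -> SyntheticDataset:
    """The default end-to-end fixture: genome, reads, counts, sequences.

    Plants ``n_circ`` back-splice junctions (single-exon circles on the
    middle exon of distinct genes).  One circle, one miRNA and the 3'UTR
    of a separate target gene form the planted ceRNA triad: two shared
    7mer-m8 seed sites embedded in both sequences, circ and mRNA
    down-regulated concordantly (log2 FC ``planted_lfc``) and tightly
    co-expressed through a shared per-sample latent factor.  Decoy
    circles/mRNAs are non-DE or DE in the opposite direction and carry
    no seed sites for any miRNA in the set, so no false triad survives
    default thresholds.
    """
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    genome, annotations = simulate_genome(
        n_genes=n_genes, exons_per_gene=3, rng_seed=int(seeds[0])
    )
    junctions = choose_planted_junctions(
        annotations, n_circ, support_range=(3, 6), rng_seed=int(seeds[1])
    )
    truth = SyntheticTruth(planted_junctions=junctions)
    chrom = genome[0]
    chrom_seq = chrom.sequence

    # --- triad members -----------------------------------------------------
    junction_ann: dict[str, ExonAnnotation] = {}
    for ann in annotations:
        mid_exon = ann.exons[len(ann.exons) // 2]
        for j in junctions:
            if mid_exon == (j.acceptor_pos, j.donor_pos):
                junction_ann[j.circ_id] = ann
    triad_junction = junctions[0]
    triad_circ_ann = junction_ann[triad_junction.circ_id]
    circ_gene_ids = {a.gene_id for a in junction_ann.values()}
    target_ann = next(a for a in annotations if a.gene_id not in circ_gene_ids)

    mir_rng = np.random.default_rng(int(seeds[2]))
    mirna = "".join(np.array(list("ACGU"))[mir_rng.integers(0, 4, size=22)])
    site, core = _site_cassette(mirna, mir_rng), _seed_core(mirna)

    # Embed two shared seed sites (transcript orientation) in the genomic
    # middle exon of the triad circle gene and the 3'UTR exon of the target
    # gene, keeping clear of the splice motifs at the exon edges.
    planted_intervals: list[tuple[int, int]] = []  # 0-based half-open genomic

    def plant_in_exon(ann: ExonAnnotation, exon: tuple[int, int], n_sites: int,
                      seq: str) -> str:
        start, end = exon
        margin = 25
        usable = (end - start + 1) - 2 * margin - len(site)
        if usable < (n_sites - 1) * (len(mirna) + 12):
            raise ValueError("exon too short to hold the planted seed sites")
        step = usable // max(n_sites, 1)
        edits = []
        for s in range(n_sites):
            offset = margin + s * step  # transcript-sense offset within the exon
            if ann.strand == "+":
                pos0 = (start - 1) + offset
                edits.append((pos0, site))
            else:
                pos0 = (end - 1) - offset - (len(site) - 1)
                edits.append((pos0, revcomp(site)))
            planted_intervals.append((edits[-1][0], edits[-1][0] + len(site)))
        return _edit_genome(seq, edits)

    triad_circ_exon = triad_circ_ann.exons[1]
    target_utr_exon = _utr_exon(target_ann)
    chrom_seq = plant_in_exon(triad_circ_ann, triad_circ_exon, 2, chrom_seq)
    chrom_seq = plant_in_exon(target_ann, target_utr_exon, 2, chrom_seq)

    # The sequences the MRE stage will scan: each planted circle's exonic
    # sequence and each gene's 3'UTR exon, in transcript orientation.
    scanned: list[tuple[tuple[int, int], str]] = []
    for j in junctions:
        ann = junction_ann[j.circ_id]
        scanned.append((ann.exons[1], ann.strand))
    for ann in annotations:
        scanned.append((_utr_exon(ann), ann.strand))

    chrom_seq = _scrub_scanned_regions(
        chrom_seq, scanned, core, planted_intervals, rng
    )
    genome = [GenomeSequence(chrom.chrom_name, chrom_seq)]

    reads = simulate_reads(
        genome,
        annotations,
        truth,
        n_linear=n_linear_reads,
        read_len=read_len,
        error_rate=error_rate,
        rng_seed=int(seeds[3]),
    )

    # --- miRNA set: the planted one plus decoys without any scanned site ---
    scanned_seqs = [_oriented_exon_seq(chrom_seq, exon, strand)
                    for exon, strand in scanned]
    mirnas = {"mir_planted": mirna}
    decoy_rng = np.random.default_rng(int(seeds[4]))
    d = 0
    while len(mirnas) < n_mirnas:
        cand = "".join(np.array(list("ACGU"))[decoy_rng.integers(0, 4, size=22)])
        cand_core = _seed_core(cand)
        if all(_count_core_matches(s, cand_core) == 0 for s in scanned_seqs):
            d += 1
            mirnas[f"mir_decoy{d}"] = cand

    # --- 3'UTR sequences for every gene ------------------------------------
    mrna_seqs = {
        ann.gene_id: _oriented_exon_seq(chrom_seq, _utr_exon(ann), ann.strand)
        for ann in annotations
    }

    # --- counts with planted DE and co-expression --------------------------
    circ_ids = [j.circ_id for j in junctions]
    gene_ids = [a.gene_id for a in annotations]
    sample_ids = [f"ctrl{i + 1}" for i in range(samples_per_group)] + [
        f"glau{i + 1}" for i in range(samples_per_group)
    ]
    group = np.array([0] * samples_per_group + [1] * samples_per_group)
    count_rng = np.random.default_rng(int(seeds[5]))

    # A shared per-sample latent factor couples the triad circ and mRNA.
    # The same replicate-wise pattern repeats in both groups, so the factor
    # creates co-expression without perturbing the group means (the planted
    # fold change stays exact); the pair is drawn abundant and nearly
    # Poisson so its planted correlation is measured faithfully at n=6 —
    # the sponge model presumes a tightly co-expressed, well-quantified
    # pair, and sampling noise should not decide whether the planted
    # structure exists.
    latent = np.tile(np.exp(count_rng.normal(0.0, 0.3, size=samples_per_group)), 2)

    def draw_counts(feature_ids, base_means, lfcs, coupled: set[str]) -> np.ndarray:
        counts = np.empty((len(feature_ids), 2 * samples_per_group), dtype=np.int64)
        for i, fid in enumerate(feature_ids):
            mu = base_means[i] * 2.0 ** (lfcs[i] * group)
            alpha = 0.01
            if fid in coupled:
                mu = np.maximum(mu, 400.0 * 2.0 ** (lfcs[i] * group)) * latent
                alpha = 0.001
            r = 1.0 / alpha
            counts[i] = count_rng.negative_binomial(r, r / (r + mu))
        return counts

    triad_circ_id = triad_junction.circ_id
    circ_lfcs = np.zeros(len(circ_ids))
    circ_lfcs[circ_ids.index(triad_circ_id)] = planted_lfc
    for k in (1, 2):  # decoy circles DE in the opposite direction
        if k < len(circ_ids):
            circ_lfcs[k] = -planted_lfc
    gene_lfcs = np.zeros(len(gene_ids))
    gene_lfcs[gene_ids.index(target_ann.gene_id)] = planted_lfc
    for k, gid in enumerate(gene_ids):
        if gid != target_ann.gene_id and k % 5 == 4:
            gene_lfcs[k] = -planted_lfc  # discordant decoy mRNAs

    circ_base = count_rng.uniform(80, 300, size=len(circ_ids))
    gene_base = count_rng.uniform(150, 600, size=len(gene_ids))
    coupled = {triad_circ_id, target_ann.gene_id}
    group_labels = {
        s: ("control" if g == 0 else "glaucoma") for s, g in zip(sample_ids, group)
    }
    circ_counts = CountMatrix(
        circ_ids, sample_ids,
        draw_counts(circ_ids, circ_base, circ_lfcs, coupled), dict(group_labels),
    )
    mrna_counts = CountMatrix(
        gene_ids, sample_ids,
        draw_counts(gene_ids, gene_base, gene_lfcs, coupled), dict(group_labels),
    )

    planted_de = {
        fid: float(l)
        for fid, l in list(zip(circ_ids, circ_lfcs)) + list(zip(gene_ids, gene_lfcs))
        if l != 0
    }
    truth.planted_de = planted_de
    truth.planted_triad = (
        triad_circ_id,
        "mir_planted",
        target_ann.gene_id,
        {"circ": [], "mrna": []},  # genomic planting; positions found by the scanner
    )
    return SyntheticDataset(
        genome=genome,
        annotations=annotations,
        reads=reads,
        mirnas=mirnas,
        mrna_seqs=mrna_seqs,
        circ_counts=circ_counts,
        mrna_counts=mrna_counts,
        truth=truth,
    )


def _edit_genome(seq: str, edits: list[tuple[int, str]]) -> str:
    """Apply (0-based position, replacement string) edits to a sequence."""
    arr = list(seq)
    for pos, repl in edits:
        arr[pos : pos + len(repl)] = repl
    return "".join(arr)


def _scrub_scanned_regions(
    chrom_seq: str,
    scanned: list[tuple[tuple[int, int], str]],
    core: str,
    planted_intervals: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> str:
    """Mutate incidental seed-core matches inside the scanned exons.

    Only the planted sites (``planted_intervals``, 0-based half-open
    genomic) may match the core after scrubbing.  Mutations stay >= 4 nt
    from exon edges so splice-site windows are untouched.
    """

    def in_planted(pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in planted_intervals)

    for _ in range(max_rounds):
        edits: list[tuple[int, str]] = []
        for (start, end), strand in scanned:
            oriented = _oriented_exon_seq(chrom_seq, (start, end), strand)
            offset = 0
            while True:
                i = oriented.find(core, offset)
                if i < 0:
                    break
                offset = i + 1
                # map the hit's middle base back to genomic 0-based position
                mid = i + 3
                if strand == "+":
                    pos0 = (start - 1) + mid
                else:
                    pos0 = (end - 1) - mid
                if in_planted(pos0):
                    continue
                # keep clear of the 3 exonic nt that feed splice windows
                if pos0 < (start - 1) + 4 or pos0 > (end - 1) - 4:
                    continue
                edits.append((pos0, ""))
        if not edits:
            return chrom_seq
        arr = list(chrom_seq)
        for pos0, _ in edits:
            choices = [b for b in "ACGT" if b != arr[pos0]]
            arr[pos0] = choices[int(rng.integers(0, 3))]
        chrom_seq = "".join(arr)
    raise RuntimeError("could not scrub incidental seed matches from the genome")
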