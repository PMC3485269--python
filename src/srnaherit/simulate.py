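"""Ground-truth-labelled synthetic small-RNA experiments.

The generator emits everything the pipeline consumes — genome FASTA,
GFF3 annotation, per-library aligned reads in the BED dialect, a design
table, a mature-miRNA database, an rRNA-decoy blocklist — plus a truth
table keyed to the planted clusters.

Statistical structure
---------------------
Each planted cluster has a low-parent expression level (``base_expression_rpm``)
and a high-parent level ``parental_fold_change`` times higher; which inbred
(CC or LL) is the high parent is random per cluster.  The hybrid mean
follows the planted inheritance pattern (additive = midparent; HP/LP = the
parent levels; AHP = 1.5x the high parent; BLP = 0.5x the low parent; the
between patterns sit at the 25%/75% quantiles of the parental range;
parent-equal clusters have no parental difference).  Per biological
replicate, the cluster's total count is negative-binomial with
``Var = m + dispersion * m^2``; the technical replicates are a binomial
split of that total, mimicking resequencing of one library.  Counts are
realised as a few distinct read species at fixed positions less than 500 bp
apart; multimapping species repeat at ``n_loci`` positions within their
cluster under a shared seq_id, so 1/N weighting conserves the planted mean.

Planted pre-miRNA loci splice an idealised 170-nt hairpin block into the
genome — a G-homopolymer mature arm, a 30-nt loop and a C-homopolymer star
arm inside inert A flanks — and emit a dominant mature read plus a minor
star read.  Under the maximum-base-pairing fold backend the designed stem
is the unique maximum structure, so hairpin ground truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .types import (
    READ_COLUMNS,
    Feature,
    GenomeAnnotation,
    bio_sample_id,
    validate_design,
    validate_reads,
)

PATTERN_CHOICES = (
    "additive", "HP", "LP", "AHP", "BLP", "between_MP_HP", "between_MP_LP",
)


def pattern_mean(pattern: str, lp: float, hp: float) -> float:
    """Hybrid mean implied by an inheritance pattern and the parent levels."""
    table = {
        "additive": (lp + hp) / 2.0,
        "HP": hp,
        "LP": lp,
        "AHP": 1.5 * hp,
        "BLP": 0.5 * lp,
        "between_MP_HP": lp + 0.75 * (hp - lp),
        "between_MP_LP": lp + 0.25 * (hp - lp),
        "parent_equal": lp,
    }
    return table[pattern]


def nb_counts(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """Negative-binomial counts with Var = mean + dispersion * mean^2.

    ``dispersion = 0`` degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated experiment.

    Defaults describe a small but fully featured experiment: 7 x 10 planted
    pattern clusters plus parent-equal nulls and two pre-miRNA loci over a
    two-chromosome toy genome, with the replication structure of the study
    design (3 inbred and 4 hybrid biological replicates, 2 technical
    replicates each).
    """

    seed: int
    clusters_per_pattern: int = 10
    parent_equal_clusters: int = 10
    mirna_loci: int = 2
    base_expression_rpm: float = 100.0
    parental_fold_change: float = 4.0
    dispersion: float = 0.1
    depth: int = 5_000_000
    bio_reps_inbred: int = 3
    bio_reps_hybrid: int = 4
    tech_reps: int = 2
    species_per_cluster: int = 4
    multimap_fraction: float = 0.2
    n_loci_choices: tuple[int, ...] = (2, 3)
    length_probs: tuple[tuple[int, float], ...] = ((21, 0.3), (24, 0.7))
    category_probs: tuple[tuple[str, float], ...] = (
        ("TE", 0.45), ("gene", 0.35), ("intergenic", 0.20),
    )
    te_within_1kb_prob: float = 0.5
    cluster_span: int = 300
    intercluster_gap: int = 1400
    n_chromosomes: int = 2
    chrom_length: int = 120_000
    n_rrna_decoys: int = 3
    mirna_rpm: float = 60.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("base_expression_rpm", "parental_fold_change", "depth",
                     "cluster_span", "intercluster_gap", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.multimap_fraction <= 1 and 0 <= self.te_within_1kb_prob <= 1):
            raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def pattern_benchmark(cls, seed: int, clusters_per_pattern: int = 200) -> "SimulationConfig":
        """The 7 x 200 pattern-recovery design.

        Sized by an a priori power analysis: with a parental fold change of
        4 at n = 3/3/4 biological replicates, separating the between
        patterns from the adjacent parent-like patterns by t-tests at
        alpha = 0.05 needs a per-sample count CV of about 5%, i.e. deep
        counts (base 100 RPM at 8M reads) with low biological dispersion
        (0.0025).  Categories are left fully intergenic and no miRNA loci
        are planted: the benchmark measures pattern recovery only.
        """
        return cls(
            seed=seed,
            clusters_per_pattern=clusters_per_pattern,
            parent_equal_clusters=0,
            mirna_loci=0,
            base_expression_rpm=100.0,
            parental_fold_change=4.0,
            dispersion=0.0025,
            depth=8_000_000,
            category_probs=(("intergenic", 1.0),),
            n_chromosomes=max(2, (clusters_per_pattern * 7 * 1800) // 450_000 + 1),
            chrom_length=450_000,
            n_rrna_decoys=0,
        )


@dataclass
class SimulatedExperiment:
    """Everything :func:`generate` produces, in memory."""

    config: SimulationConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    reads: pd.DataFrame          # all libraries, decoy rRNA rows included
    design: pd.DataFrame
    mirna_db: dict[str, str]
    blocklist: frozenset[str]
    truth: pd.DataFrame          # planted interval, pattern, category, flags


# hairpin block geometry (offsets within the 170-nt planted block)
_HAIRPIN_LEN = 170
_MATURE_OFF, _MATURE_LEN = 75, 21
_LOOP_LEN = 30
_STAR_OFF = _MATURE_OFF + _MATURE_LEN + _LOOP_LEN  # 126


def _hairpin_block() -> str:
    block = (
        "A" * _MATURE_OFF
        + "G" * _MATURE_LEN
        + "A" * _LOOP_LEN
        + "C" * _MATURE_LEN
        + "A" * (_HAIRPIN_LEN - _STAR_OFF - _MATURE_LEN)
    )
    assert len(block) == _HAIRPIN_LEN
    return block


def _random_genome(rng: np.random.Generator, config: SimulationConfig) -> dict[str, str]:
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    return {
        f"chr{i + 1}": alphabet[rng.integers(0, 4, config.chrom_length)].tobytes().decode()
        for i in range(config.n_chromosomes)
    }


def make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for genotype in ("CC", "LL", "CL", "LC"):
        n_bio = config.bio_reps_inbred if genotype in ("CC", "LL") else config.bio_reps_hybrid
        for bio in range(1, n_bio + 1):
            for tech in range(1, config.tech_reps + 1):
                rows.append(
                    {
                        "library_id": f"{genotype}_b{bio}_t{tech}",
                        "genotype": genotype,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "total_mapped_reads": config.depth,
                    }
                )
    return validate_design(pd.DataFrame(rows))


def generate(config: SimulationConfig) -> SimulatedExperiment:
    """Draw one complete synthetic experiment from the configured conditions."""
    rng = np.random.default_rng(config.seed)
    design = make_design(config)
    genome = _random_genome(rng, config)

    # --- plan the clusters -------------------------------------------------
    plan = []
    for pattern in PATTERN_CHOICES:
        plan += [{"pattern": pattern, "is_mirna": False}] * config.clusters_per_pattern
    plan += [{"pattern": "parent_equal", "is_mirna": False}] * config.parent_equal_clusters
    plan += [{"pattern": "parent_equal", "is_mirna": True}] * config.mirna_loci
    rng.shuffle(plan)

    cats, probs = zip(*config.category_probs)
    pitch = config.cluster_span + config.intercluster_gap
    margin = 1000
    per_chrom = (config.chrom_length - 2 * margin) // pitch
    if per_chrom * config.n_chromosomes < len(plan):
        raise ValueError(
            f"{len(plan)} clusters do not fit {config.n_chromosomes} chromosomes "
            f"of {config.chrom_length} bp at a {pitch} bp pitch"
        )

    chrom_names = list(genome)
    features: list[Feature] = []
    truth_rows = []
    read_cols: dict[str, list] = {c: [] for c in READ_COLUMNS}
    lib_meta = design[["library_id", "genotype", "bio_rep", "tech_rep"]]
    bio_groups = list(lib_meta.groupby(["genotype", "bio_rep"], sort=True))
    length_values, length_p = zip(*config.length_probs)

    mirna_db: dict[str, str] = {}
    mirna_index = 0

    def emit_reads(species, counts_per_library):
        """Append BED rows for one cluster's species across all libraries."""
        for lib, per_species in counts_per_library.items():
            for sp, abundance in zip(species, per_species):
                if abundance <= 0:
                    continue
                for start, end in sp["loci"]:
                    read_cols["seq_id"].append(sp["seq_id"])
                    read_cols["chrom"].append(sp["chrom"])
                    read_cols["start"].append(start)
                    read_cols["end"].append(end)
                    read_cols["strand"].append(sp["strand"])
                    read_cols["length"].append(sp["length"])
                    read_cols["abundance"].append(abundance)
                    read_cols["n_loci"].append(len(sp["loci"]))
                    read_cols["library_id"].append(lib)

    def genotype_means(pattern):
        lp = config.base_expression_rpm
        hp = lp * config.parental_fold_change
        if pattern == "parent_equal":
            hybrid = pattern_mean(pattern, lp, lp)
            return {"CC": lp, "LL": lp, "CL": hybrid, "LC": hybrid}
        hybrid = pattern_mean(pattern, lp, hp)
        if rng.random() < 0.5:
            return {"CC": hp, "LL": lp, "CL": hybrid, "LC": hybrid}
        return {"CC": lp, "LL": hp, "CL": hybrid, "LC": hybrid}

    def draw_counts(mean_rpm_by_genotype):
        """Tech-library totals for one cluster: NB per biological sample,
        binomially split over its technical replicates."""
        out = {}
        for (genotype, _bio), sub in bio_groups:
            lam = mean_rpm_by_genotype[genotype] * config.depth / 1e6
            total = int(nb_counts(rng, config.tech_reps * lam, config.dispersion))
            libs = list(sub["library_id"])
            split = rng.multinomial(total, np.full(len(libs), 1.0 / len(libs)))
            for lib, c in zip(libs, split):
                out[lib] = int(c)
        return out

    for idx, entry in enumerate(plan):
        chrom = chrom_names[idx // per_chrom]
        start = margin + (idx % per_chrom) * pitch
        end = start + config.cluster_span

        if entry["is_mirna"]:
            mirna_index += 1
            block_start = start
            seq = genome[chrom]
            genome[chrom] = seq[:block_start] + _hairpin_block() + seq[block_start + _HAIRPIN_LEN:]
            m_start = block_start + _MATURE_OFF
            s_start = block_start + _STAR_OFF
            mature = {
                "seq_id": f"mir{mirna_index}_mature", "chrom": chrom, "strand": "+",
                "length": _MATURE_LEN, "loci": [(m_start, m_start + _MATURE_LEN)],
            }
            star = {
                "seq_id": f"mir{mirna_index}_star", "chrom": chrom, "strand": "+",
                "length": _MATURE_LEN, "loci": [(s_start, s_start + _MATURE_LEN)],
            }
            mirna_db[f"mir{mirna_index}"] = "G" * _MATURE_LEN
            counts = draw_counts({gt: config.mirna_rpm for gt in ("CC", "LL", "CL", "LC")})
            split = {
                lib: (int(round(c * 5 / 6)), c - int(round(c * 5 / 6))) for lib, c in counts.items()
            }
            emit_reads([mature, star], split)
            truth_rows.append(
                {
                    "chrom": chrom, "start": m_start, "end": s_start + _MATURE_LEN,
                    "pattern": "parent_equal", "category": "intergenic",
                    "te_within_1kb": False, "is_mirna": True,
                }
            )
            continue

        category = cats[int(rng.choice(len(cats), p=probs))]
        te_flag = False
        cid = f"sim{idx}"
        if category == "TE":
            features.append(Feature(f"TE_{cid}", "transposable_element", chrom, start - 20, end + 20, "+"))
        elif category == "gene":
            gene = Feature(f"gene_{cid}", "gene", chrom, start - 20, end + 20, "+")
            mid = (start + end) // 2
            features += [
                gene,
                Feature(f"cds1_{cid}", "CDS", chrom, start - 20, mid - 30, "+", parent_id=gene.feature_id),
                Feature(f"intron_{cid}", "intron", chrom, mid - 30, mid + 30, "+", parent_id=gene.feature_id),
                Feature(f"cds2_{cid}", "CDS", chrom, mid + 30, end + 20, "+", parent_id=gene.feature_id),
            ]
            te_flag = bool(rng.random() < config.te_within_1kb_prob)
            if te_flag:
                features.append(
                    Feature(f"TEnear_{cid}", "transposable_element", chrom, end + 220, end + 320, "+")
                )

        # read species: fixed positions inside the cluster, weights shared
        # across libraries; multimapping species repeat within the cluster
        n_sp = config.species_per_cluster
        offsets = np.linspace(0, config.cluster_span - 31, n_sp).astype(int)
        weights = rng.dirichlet(np.full(n_sp, 2.0))
        species = []
        for s_i in range(n_sp):
            length = int(rng.choice(length_values, p=length_p))
            pos = start + int(offsets[s_i])
            loci = [(pos, pos + length)]
            if rng.random() < config.multimap_fraction and n_sp > 1:
                n_loci = int(rng.choice(config.n_loci_choices))
                for extra in range(1, n_loci):
                    alt = start + int((offsets[s_i] + extra * 13 + 31) % (config.cluster_span - 31))
                    loci.append((alt, alt + length))
                loci = sorted(set(loci))
            species.append(
                {
                    "seq_id": f"{cid}_s{s_i}", "chrom": chrom,
                    "strand": "+" if s_i % 2 == 0 else "-",
                    "length": length, "loci": loci,
                }
            )
        counts = draw_counts(genotype_means(entry["pattern"]))
        per_lib = {lib: rng.multinomial(c, weights) for lib, c in counts.items()}
        emit_reads(species, per_lib)
        truth_rows.append(
            {
                "chrom": chrom, "start": start, "end": end,
                "pattern": entry["pattern"], "category": category,
                "te_within_1kb": te_flag, "is_mirna": False,
            }
        )

    # --- rRNA decoys -------------------------------------------------------
    blocklist = set()
    for d in range(config.n_rrna_decoys):
        sid = f"rrna_decoy{d + 1}"
        blocklist.add(sid)
        pos = 100 + d * 60
        decoy = {
            "seq_id": sid, "chrom": chrom_names[0], "strand": "+",
            "length": 24, "loci": [(pos, pos + 24)],
        }
        counts = {lib: int(nb_counts(rng, 200, config.dispersion)) + 1 for lib in design["library_id"]}
        emit_reads([decoy], {lib: [c] for lib, c in counts.items()})

    # a couple of unrelated db entries so matching is not vacuous
    alphabet = np.array(list("ACGU"))
    for d in range(2):
        mirna_db[f"decoy_mir{d + 1}"] = "".join(alphabet[rng.integers(0, 4, 21)])

    reads = pd.DataFrame(read_cols)
    validate_reads(reads)
    annotation = GenomeAnnotation(
        chromosomes={name: len(seq) for name, seq in genome.items()}, features=features
    )
    annotation.validate()
    truth = pd.DataFrame(truth_rows)
    truth.index.name = "planted_id"
    return SimulatedExperiment(
        config=config,
        genome=genome,
        annotation=annotation,
        reads=reads,
        design=design,
        mirna_db=mirna_db,
        blocklist=frozenset(blocklist),
        truth=truth,
    )


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write an experiment to disk in exactly the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fasta"
    io_formats.write_fasta(exp.genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    io_formats.write_gff(exp.annotation, paths["annotation"])
    paths["design"] = outdir / "design.tsv"
    io_formats.write_design(exp.design, paths["design"])
    paths["mirna_db"] = outdir / "mirna_db.fasta"
    io_formats.write_fasta(exp.mirna_db, paths["mirna_db"])
    paths["blocklist"] = outdir / "blocklist.txt"
    io_formats.write_blocklist(exp.blocklist, paths["blocklist"])
    paths["truth"] = outdir / "truth.tsv"
    exp.truth.to_csv(paths["truth"], sep="\t")
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for lib, sub in exp.reads.groupby("library_id"):
        p = reads_dir / f"{lib}.bed"
        io_formats.write_alignments(sub, p)
        paths[f"reads/{lib}"] = p
    return paths


# ---------------------------------------------------------------------------
# Deterministic worked example
# ---------------------------------------------------------------------------

#: Biological-replicate multipliers applied to each genotype mean; chosen so
#: that all planted means of the worked example realise integer counts.
_INBRED_MULT = (0.95, 1.0, 1.05)
_HYBRID_MULT = (0.95, 1.0, 1.05, 1.0)

_WE_LP, _WE_HP = 80, 320


def worked_example() -> SimulatedExperiment:
    """A fixed 2-chromosome, 12-cluster dataset with no randomness.

    Exercises each inheritance pattern and each annotation category once,
    a cross-cluster multimapping pair, a cluster sitting exactly on the
    5-RPM expression boundary, and one planted pre-miRNA hairpin.  Library
    depth is 1e6, so raw counts equal RPM.
    """
    lp, hp = _WE_LP, _WE_HP
    specs = [
        # cluster chrom  start   pattern           category        te1kb means(CC, LL, H)
        ("c01", "chr1", 1000, "additive",       "TE",            None, (hp, lp, 200)),
        ("c02", "chr1", 3000, "AHP",            "TE",            None, (hp, lp, 480)),
        ("c03", "chr1", 5000, "LP",             "gene",          False, (hp, lp, 80)),
        ("c04", "chr1", 7000, "HP",             "gene",          True, (hp, lp, 320)),
        ("c05", "chr1", 9000, "BLP",            "near_TE_500",   None, (hp, lp, 40)),
        ("c06", "chr1", 11000, "between_MP_LP", "near_gene_500", False, (hp, lp, 140)),
        ("c07", "chr1", 13000, "between_MP_HP", "intergenic",    None, (hp, lp, 260)),
        ("c12", "chr2", 9000, "LP",             "TE",            None, (lp, hp, 80)),
    ]
    chrom_lengths = {"chr1": 16000, "chr2": 12000}
    design = make_design(
        SimulationConfig(seed=0, depth=1_000_000, bio_reps_inbred=3, bio_reps_hybrid=4, tech_reps=2)
    )

    read_cols: dict[str, list] = {c: [] for c in READ_COLUMNS}

    def add_row(seq_id, chrom, start, length, strand, abundance, n_loci, lib):
        read_cols["seq_id"].append(seq_id)
        read_cols["chrom"].append(chrom)
        read_cols["start"].append(start)
        read_cols["end"].append(start + length)
        read_cols["strand"].append(strand)
        read_cols["length"].append(length)
        read_cols["abundance"].append(abundance)
        read_cols["n_loci"].append(n_loci)
        read_cols["library_id"].append(lib)

    def per_library_totals(means):
        mean_cc, mean_ll, mean_h = means
        totals = {}
        for row in design.itertuples():
            if row.genotype == "CC":
                value = mean_cc * _INBRED_MULT[row.bio_rep - 1]
            elif row.genotype == "LL":
                value = mean_ll * _INBRED_MULT[row.bio_rep - 1]
            else:
                value = mean_h * _HYBRID_MULT[row.bio_rep - 1]
            totals[row.library_id] = int(round(value))
        return totals

    # --- seven pattern clusters + the reversed-parent TE cluster -----------
    for cid, chrom, start, _pattern, _category, _te1kb, means in specs:
        totals = per_library_totals(means)
        for lib, total in totals.items():
            quarter = total // 4
            split = [total - 2 * quarter, quarter, quarter]
            for s_i, (offset, length, strand, abundance) in enumerate(
                zip((0, 80, 160), (24, 21, 24), ("+", "-", "+"), split)
            ):
                if abundance > 0:
                    add_row(f"{cid}_s{s_i}", chrom, start + offset, length, strand, abundance, 1, lib)

    # --- parent-equal pair sharing a multimapping species (c08/c09) --------
    for lib in design["library_id"]:
        add_row("mm_shared", "chr2", 1000, 24, "+", 16, 2, lib)
        add_row("mm_shared", "chr2", 3000, 24, "+", 16, 2, lib)
        add_row("c08_own", "chr2", 1060, 24, "-", 4, 1, lib)
        add_row("c09_own", "chr2", 3060, 21, "+", 4, 1, lib)

    # --- boundary cluster: maximum sample expression exactly 5 RPM ---------
    boundary = {"CC": (5, 4, 5), "LL": (4, 5, 4), "CL": (5, 4, 5, 4), "LC": (4, 5, 4, 5)}
    for row in design.itertuples():
        add_row("c10_s0", "chr2", 5000, 24, "+", boundary[row.genotype][row.bio_rep - 1], 1, row.library_id)

    # --- planted pre-miRNA (c11) -------------------------------------------
    block_start = 7000
    m_start = block_start + _MATURE_OFF
    s_start = block_start + _STAR_OFF
    for lib in design["library_id"]:
        add_row("mir1_mature", "chr2", m_start, _MATURE_LEN, "+", 50, 1, lib)
        add_row("mir1_star", "chr2", s_start, _MATURE_LEN, "+", 10, 1, lib)

    # --- rRNA decoys (blocklisted) ------------------------------------------
    blocklist = frozenset({"rrna_decoy1", "rrna_decoy2"})
    for lib in design["library_id"]:
        add_row("rrna_decoy1", "chr2", 300, 24, "+", 100, 1, lib)
        add_row("rrna_decoy2", "chr2", 400, 24, "+", 80, 1, lib)

    # --- genome -------------------------------------------------------------
    genome = {name: "A" * length for name, length in chrom_lengths.items()}
    chr2 = genome["chr2"]
    genome["chr2"] = chr2[:block_start] + _hairpin_block() + chr2[block_start + _HAIRPIN_LEN:]

    # --- annotation ---------------------------------------------------------
    features = [
        Feature("TE_c01", "transposable_element", "chr1", 980, 1220, "+"),
        Feature("TE_c02", "transposable_element", "chr1", 2980, 3220, "+"),
        Feature("gene_c03", "gene", "chr1", 4980, 5220, "+"),
        Feature("cds_c03a", "CDS", "chr1", 4980, 5080, "+", parent_id="gene_c03"),
        Feature("intron_c03", "intron", "chr1", 5080, 5120, "+", parent_id="gene_c03"),
        Feature("cds_c03b", "CDS", "chr1", 5120, 5220, "+", parent_id="gene_c03"),
        Feature("gene_c04", "gene", "chr1", 6980, 7220, "+"),
        Feature("cds_c04", "CDS", "chr1", 6980, 7220, "+", parent_id="gene_c04"),
        Feature("TE_c04n", "transposable_element", "chr1", 7420, 7520, "+"),
        Feature("TE_c05n", "transposable_element", "chr1", 9400, 9500, "+"),
        Feature("gene_c06", "gene", "chr1", 10600, 10800, "+"),
        Feature("cds_c06", "CDS", "chr1", 10600, 10800, "+", parent_id="gene_c06"),
        Feature("TE_c12", "transposable_element", "chr2", 8980, 9220, "+"),
    ]
    annotation = GenomeAnnotation(chromosomes=chrom_lengths, features=features)
    annotation.validate()

    truth = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": s + 200, "pattern": p, "category": cat,
             "te_within_1kb": bool(t) if t is not None else False, "is_mirna": False}
            for _cid, c, s, p, cat, t, _m in specs
        ]
        + [
            {"chrom": "chr2", "start": 1000, "end": 1084, "pattern": "parent_equal",
             "category": "intergenic", "te_within_1kb": False, "is_mirna": False},
            {"chrom": "chr2", "start": 3000, "end": 3084, "pattern": "parent_equal",
             "category": "intergenic", "te_within_1kb": False, "is_mirna": False},
            {"chrom": "chr2", "start": 5000, "end": 5024, "pattern": "parent_equal",
             "category": "intergenic", "te_within_1kb": False, "is_mirna": False},
            {"chrom": "chr2", "start": m_start, "end": s_start + _MATURE_LEN,
             "pattern": "parent_equal", "category": "intergenic",
             "te_within_1kb": False, "is_mirna": True},
        ]
    )
    truth.index.name = "planted_id"

    reads = pd.DataFrame(read_cols)
    validate_reads(reads)
    config = SimulationConfig(seed=0, depth=1_000_000)
    return SimulatedExperiment(
        config=config,
        genome=genome,
        annotation=annotation,
        reads=reads,
        design=design,
        mirna_db={"mir1": "G" * _MATURE_LEN, "decoy_mir1": "ACGUACGUACGUACGUACGUA"},
        blocklist=blocklist,
        truth=truth,
    )


def match_truth_to_clusters(truth: pd.DataFrame, clusters: pd.DataFrame) -> pd.Series:
    """Map each planted cluster to the detected cluster overlapping it.

    Returns a Series of cluster_ids indexed like ``truth`` (NaN when no
    detected cluster overlaps the planted interval).
    """
    out = pd.Series(index=truth.index, dtype=object)
    for pid, row in truth.iterrows():
        sub = clusters[
            (clusters["chrom"] == row["chrom"])
            & (clusters["start"] < row["end"])
            & (clusters["end"] > row["start"])
        ]
        if len(sub):
            out.loc[pid] = sub.iloc[0]["cluster_id"]
    return out
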