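"""miRNA-like screening of small-RNA clusters.

A cluster is miRNA-like when its highest-expressed read sits on one arm of
a fold-back (hairpin) structure in the surrounding genomic window.  The
screen takes the top read of the cluster, extracts a strand-specific 170-nt
window centred on it, folds the window, and tests the mature/star geometry:

* folding free energy at most -40 (kcal/mol with a thermodynamic backend;
  the built-in backend reports a proxy of -2.0 per base pair),
* at least 75% of the read's bases paired,
* the paired complement (the predicted miRNA*) spans at most 1.5x the read
  length,
* at least 20 nt between the read and its complement (the hairpin loop),
* no base of the read, nor within 10 nt of its ends, pairs inside that same
  neighbourhood (the read must not fold onto itself).

The folding backend is pluggable: any callable mapping a sequence to a
``(dot_bracket, dG)`` pair works (e.g. an RNAfold wrapper).  The default is
a Nussinov-style maximum base-pairing fold (Watson-Crick + GU wobble,
minimum loop 3) whose dG proxy counts -2.0 kcal/mol per pair; with it the
dG criterion is applied to the proxy value.

Known-miRNA matching runs a full Smith-Waterman local alignment of the top
read against a mature-miRNA database, with significance from an empirical
shuffle null in place of a fitted extreme-value p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")

#: Base pairs accepted by the default fold (DNA alphabet; T == U).
_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

DEFAULT_WINDOW = 170
DEFAULT_DG_CUTOFF = -40.0
DEFAULT_PAIRED_FRACTION = 0.75
DEFAULT_STAR_FACTOR = 1.5
DEFAULT_LOOP_DISTANCE = 20
SELF_PAIR_MARGIN = 10


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Top read and window extraction
# ---------------------------------------------------------------------------

def top_read(member_reads: pd.DataFrame) -> pd.Series:
    """Highest-abundance read of a cluster; ties go to the leftmost locus."""
    if len(member_reads) == 0:
        raise ValueError("empty cluster has no top read")
    ordered = member_reads.sort_values(
        ["abundance", "start", "seq_id"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.iloc[0]


@dataclass(frozen=True)
class HairpinWindow:
    seq: str          # window sequence, read-strand orientation
    read_offset: int  # start of the read within seq
    read_length: int
    clipped: bool     # True when the window hit a chromosome edge


def extract_window(
    genome: dict[str, str],
    chrom: str,
    start: int,
    end: int,
    strand: str,
    window: int = DEFAULT_WINDOW,
) -> HairpinWindow:
    """Strand-specific genomic window centred on the read midpoint.

    Minus-strand reads get the reverse complement, with the read offset
    transformed accordingly.  Windows clipped at a chromosome edge are
    flagged.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} missing from the genome")
    chrom_seq = genome[chrom]
    mid = (start + end) // 2
    win_start = mid - window // 2
    win_end = win_start + window
    clipped = win_start < 0 or win_end > len(chrom_seq)
    win_start_c = max(win_start, 0)
    win_end_c = min(win_end, len(chrom_seq))
    seq = chrom_seq[win_start_c:win_end_c].upper()
    read_offset = start - win_start_c
    read_length = end - start
    if strand == "-":
        seq = reverse_complement(seq)
        read_offset = len(seq) - (end - win_start_c)
    return HairpinWindow(seq=seq, read_offset=read_offset, read_length=read_length, clipped=clipped)


# ---------------------------------------------------------------------------
# Default folding backend: maximum base pairing
# ---------------------------------------------------------------------------

def nussinov_fold(seq: str, min_loop: int = 3) -> tuple[str, float]:
    """Maximum base-pairing fold with a -2.0 kcal/mol-per-pair energy proxy.

    Dynamic programme over all nested structures allowing Watson-Crick and
    GU wobble pairs with a minimum hairpin loop of ``min_loop`` unpaired
    bases.  Returns the dot-bracket string and the proxy energy.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n == 0:
        return "", 0.0
    can_pair = [
        [(s[i], s[j]) in _CANONICAL for j in range(n)] for i in range(n)
    ]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j - 1] + 1 if can_pair[i][j] else -1
            if dp[i + 1, j] > best:
                best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            row = dp[i]
            for k in range(i + min_loop + 1, j):
                if can_pair[i][k]:
                    v = dp[i + 1, k - 1] + 1 + dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        if can_pair[i][j] and dp[i, j] == dp[i + 1, j - 1] + 1:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + min_loop + 1, j):
            if can_pair[i][k] and dp[i, j] == dp[i + 1, k - 1] + 1 + dp[k + 1, j]:
                structure[i], structure[k] = "(", ")"
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
    n_pairs = structure.count("(")
    return "".join(structure), -2.0 * n_pairs


def pairing_map(structure: str) -> dict[int, int]:
    """Position -> partner map from a dot-bracket string."""
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


# ---------------------------------------------------------------------------
# Hairpin criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinAssessment:
    structure: str
    dg: float
    paired_fraction: float
    star_length: int
    loop_distance: int
    self_pairing: bool
    clipped: bool
    pass_dg: bool
    pass_paired: bool
    pass_star: bool
    pass_loop: bool
    pass_self: bool

    @property
    def verdict(self) -> bool:
        return (
            self.pass_dg and self.pass_paired and self.pass_star
            and self.pass_loop and self.pass_self
        )


def evaluate_hairpin(
    window: HairpinWindow,
    fold_backend=nussinov_fold,
    dg_cutoff: float = DEFAULT_DG_CUTOFF,
    paired_fraction: float = DEFAULT_PAIRED_FRACTION,
    star_factor: float = DEFAULT_STAR_FACTOR,
    loop_distance: int = DEFAULT_LOOP_DISTANCE,
    structure: str | None = None,
    dg: float | None = None,
) -> HairpinAssessment:
    """Apply the miRNA-precursor criteria to a folded window.

    An externally computed fold may be supplied through ``structure``/``dg``
    (dot-bracket of the same length as the window); otherwise
    ``fold_backend`` is called on the window sequence.
    """
    if structure is None:
        structure, dg = fold_backend(window.seq)
    if dg is None:
        raise ValueError("an external structure needs an accompanying dG")
    if len(structure) != len(window.seq):
        raise ValueError(
            f"structure length {len(structure)} != window length {len(window.seq)}"
        )
    pairs = pairing_map(structure)
    rs, re = window.read_offset, window.read_offset + window.read_length
    read_positions = range(rs, re)
    partners = sorted(pairs[i] for i in read_positions if i in pairs)
    n_paired = len(partners)
    frac = n_paired / window.read_length if window.read_length else 0.0
    if partners:
        star_lo, star_hi = partners[0], partners[-1] + 1  # half-open star span
        star_length = star_hi - star_lo
        if star_lo >= re:
            loop = star_lo - re
        elif star_hi <= rs:
            loop = rs - star_hi
        else:
            loop = 0  # star overlaps the read
    else:
        star_length = 0
        loop = 0
    ext_lo, ext_hi = rs - SELF_PAIR_MARGIN, re + SELF_PAIR_MARGIN
    self_pairing = any(
        ext_lo <= i < ext_hi and ext_lo <= j < ext_hi for i, j in pairs.items() if i < j
    )
    return HairpinAssessment(
        structure=structure,
        dg=float(dg),
        paired_fraction=frac,
        star_length=star_length,
        loop_distance=loop,
        self_pairing=self_pairing,
        clipped=window.clipped,
        pass_dg=dg <= dg_cutoff,
        pass_paired=frac >= paired_fraction,
        pass_star=0 < star_length <= star_factor * window.read_length,
        pass_loop=loop >= loop_distance,
        pass_self=not self_pairing,
    )


# ---------------------------------------------------------------------------
# Known-miRNA matching
# ---------------------------------------------------------------------------

def _sw_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -4
    return aligner


@dataclass(frozen=True)
class MirnaHit:
    mirna_id: str
    score: float
    p_value: float


def match_known_mirna(
    seq: str,
    mirna_db: dict[str, str],
    p_cutoff: float = 0.001,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> MirnaHit | None:
    """Best local-alignment hit of a read against a mature-miRNA database.

    Scores full Smith-Waterman local alignments (match +5, mismatch -4, gap
    open -10, extend -4).  Significance comes from an empirical null: the
    query is shuffled ``n_shuffles`` times and p is the fraction of shuffled
    best-database scores at least as large as the observed best score.
    Returns the hit only when p < ``p_cutoff``.
    """
    if len(seq) < 16:
        raise ValueError("query shorter than 16 nt")
    if not mirna_db:
        return None
    if rng is None:
        rng = np.random.default_rng(0)
    aligner = _sw_aligner()
    seq = seq.upper().replace("U", "T")
    db = {name: s.upper().replace("U", "T") for name, s in mirna_db.items()}
    scores = {name: aligner.score(seq, s) for name, s in db.items()}
    best_name = max(scores, key=lambda n: (scores[n], n))
    best = scores[best_name]
    letters = np.array(list(seq))
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = "".join(rng.permutation(letters))
        null_best = max(aligner.score(shuffled, s) for s in db.values())
        if null_best >= best:
            exceed += 1
    p = exceed / n_shuffles
    if p < p_cutoff:
        return MirnaHit(mirna_id=best_name, score=float(best), p_value=p)
    return None


# ---------------------------------------------------------------------------
# Cluster-level screen
# ---------------------------------------------------------------------------

def read_sequence(genome: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    """Sequence of a perfectly mapped read, from the genome."""
    seq = genome[chrom][start:end].upper()
    return reverse_complement(seq) if strand == "-" else seq


def screen_clusters(
    clusters: pd.DataFrame,
    reads: pd.DataFrame,
    genome: dict[str, str],
    mirna_db: dict[str, str] | None = None,
    fold_backend=nussinov_fold,
    window: int = DEFAULT_WINDOW,
    rng: np.random.Generator | None = None,
    **criteria,
) -> pd.DataFrame:
    """Hairpin screen (and optional known-miRNA match) per cluster.

    ``reads`` holds the member loci of the given clusters pooled over
    libraries.  Returns one row per cluster with the top read, the hairpin
    criteria booleans, the verdict and any database hit.
    """
    from .clustering import assign_reads

    work = reads.copy()
    work["_cluster"] = assign_reads(clusters, work, strict=False)
    work = work[work["_cluster"].notna()]
    rows = []
    for cluster in clusters.itertuples():
        members = work[work["_cluster"] == cluster.cluster_id]
        if len(members) == 0:
            continue
        pooled = (
            members.groupby(["seq_id", "chrom", "start", "end", "strand", "length", "n_loci"], as_index=False)["abundance"].sum()
        )
        top = top_read(pooled)
        win = extract_window(
            genome, top["chrom"], int(top["start"]), int(top["end"]), top["strand"], window=window
        )
        assessment = evaluate_hairpin(win, fold_backend=fold_backend, **criteria)
        rec = {
            "cluster_id": cluster.cluster_id,
            "top_seq_id": top["seq_id"],
            "top_start": int(top["start"]),
            "top_strand": top["strand"],
            "dg": assessment.dg,
            "paired_fraction": assessment.paired_fraction,
            "star_length": assessment.star_length,
            "loop_distance": assessment.loop_distance,
            "pass_dg": assessment.pass_dg,
            "pass_paired": assessment.pass_paired,
            "pass_star": assessment.pass_star,
            "pass_loop": assessment.pass_loop,
            "pass_self": assessment.pass_self,
            "clipped": assessment.clipped,
            "mirna_like": assessment.verdict,
            "known_mirna": "",
            "known_mirna_p": float("nan"),
        }
        if mirna_db:
            seq = read_sequence(genome, top["chrom"], int(top["start"]), int(top["end"]), top["strand"])
            hit = match_known_mirna(seq, mirna_db, rng=rng)
            if hit is not None:
                rec["known_mirna"] = hit.mirna_id
                rec["known_mirna_p"] = hit.p_value
        rows.append(rec)
    return pd.DataFrame(rows).set_index("cluster_id")
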