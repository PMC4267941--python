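"""Position weight matrices: I/O, exact score thresholds, scanning, merging.

A putative cis-regulatory element (pCRE) is represented as a PWM over ACGT.
Mapping a PWM to promoters uses a log-odds score against a 0-order
background, with the score threshold chosen so that the probability of a
random background L-mer reaching it is at most a target p-value (default
1e-5).  That tail probability is computed exactly by dynamic programming
over discretized scores, the standard approach for PWM p-values.  Redundant
motifs are merged by UPGMA on a best-offset column-correlation distance.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Motif",
    "read_meme_minimal",
    "write_meme_minimal",
    "pwm_pvalue_threshold",
    "ScanThreshold",
    "scan_promoters",
    "merge_motifs_upgma",
    "kmer_enrichment_finder",
    "reverse_complement",
]

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
# granularity of score discretization for the exact-tail DP; the total
# rounding error of an L-mer score is bounded by L * granularity / 2
SCORE_GRANULARITY = 1e-3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Motif:
    """A PWM with probabilities (4 x L, rows in ACGT order)."""

    id: str
    pwm: np.ndarray
    pseudocount: float = 0.01
    phase: float | None = None  # assigned after enrichment

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (ACGT)")
        if self.length < 4:
            raise ValueError("motif must be at least 4 columns")
        colsums = self.pwm.sum(axis=0)
        if not np.allclose(colsums, 1, atol=1e-3):
            raise ValueError("PWM columns must sum to 1")
        self.pwm = self.pwm / colsums  # exact renormalization

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.pwm.argmax(axis=0))

    def probabilities(self) -> np.ndarray:
        """PWM with pseudocounts folded in (entries strictly inside (0,1))."""
        p = self.pwm + self.pseudocount
        return p / p.sum(axis=0)

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or (background <= 0).any():
            raise ValueError("background must be 4 positive frequencies")
        background = background / background.sum()
        return np.log2(self.probabilities() / background[:, None])

    def reverse_complement(self) -> "Motif":
        return Motif(self.id + "_rc", self.pwm[::-1, ::-1], self.pseudocount,
                     self.phase)

    @classmethod
    def from_consensus(cls, id: str, consensus: str, strength: float = 0.97) -> "Motif":
        """Near-consensus PWM: the consensus base gets ``strength`` mass."""
        L = len(consensus)
        pwm = np.full((4, L), (1 - strength) / 3)
        for j, b in enumerate(consensus.upper()):
            pwm[ALPHABET.index(b), j] = strength
        return cls(id, pwm)


# ---------------------------------------------------------------------------
# MEME-minimal text I/O
# ---------------------------------------------------------------------------


def write_meme_minimal(motifs: list[Motif], path) -> None:
    """Write PWMs as minimal MEME-format text."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= 10000 E= 0\n"
            )
            for col in m.pwm.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme_minimal(path) -> list[Motif]:
    """Read PWMs from minimal MEME-format text (via Biopython)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    out = []
    for m in record:
        pwm = np.array([m.pwm[b] for b in ALPHABET])
        out.append(Motif(m.name, pwm))
    return out


# ---------------------------------------------------------------------------
# Exact p-value score threshold
# ---------------------------------------------------------------------------


@dataclass
class ScanThreshold:
    """A motif's integer score matrix and calibrated threshold.

    Scores are log-odds (bits) discretized at ``granularity``; both the
    threshold DP and promoter scanning use the same integer scores, so the
    calibrated tail probability applies exactly to the scanner.
    """

    motif: Motif
    int_scores: np.ndarray  # 4 x L integer score matrix
    threshold_int: int
    granularity: float
    pvalue: float
    attained_p: float

    @property
    def threshold(self) -> float:
        return self.threshold_int * self.granularity


def _int_scores(motif: Motif, background: np.ndarray, granularity: float) -> np.ndarray:
    return np.round(motif.log_odds(background) / granularity).astype(np.int64)


def _score_distribution(int_scores: np.ndarray, background: np.ndarray):
    """Exact distribution of the integer score of a random background L-mer.

    Returns (offset, probs) where probs[i] = P(score == offset + i).
    """
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    lo = int(int_scores.min(axis=0).sum())
    hi = int(int_scores.max(axis=0).sum())
    probs = np.zeros(hi - lo + 1)
    # running support [cur_lo, cur_lo + len(cur) - 1]
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(int_scores.shape[1]):
        col = int_scores[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + int(col[b]) - new_lo
            new[shift : shift + len(cur)] += background[b] * cur
        cur, cur_lo = new, new_lo
    probs[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    return lo, probs


def pwm_pvalue_threshold(
    motif: Motif,
    background: np.ndarray | None = None,
    p: float = 1e-5,
    granularity: float = SCORE_GRANULARITY,
) -> ScanThreshold:
    """Smallest log-odds score whose background tail probability is <= p.

    The distribution of the score of one random L-mer under the 0-order
    background is computed exactly by DP; raises if even the maximal score
    is reached with probability greater than ``p`` (the motif is too short
    or too degenerate to attain the requested p-value).
    """
    background = np.array([0.25] * 4) if background is None else np.asarray(background)
    scores = _int_scores(motif, background, granularity)
    lo, probs = _score_distribution(scores, background)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= lo + i)
    attainable = np.flatnonzero(tail <= p)
    if attainable.size == 0:
        min_tail = tail[np.flatnonzero(probs)[-1]]
        raise ValueError(
            f"p-value {p:g} unattainable for motif {motif.id!r} "
            f"(minimum tail probability {min_tail:.3g})"
        )
    i = int(attainable[0])
    return ScanThreshold(
        motif=motif,
        int_scores=scores,
        threshold_int=lo + i,
        granularity=granularity,
        pvalue=p,
        attained_p=float(tail[i]),
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_one(codes: np.ndarray, st: ScanThreshold) -> list[tuple[int, int]]:
    """(offset, int score) of every window at or above the threshold."""
    L = st.int_scores.shape[1]
    n = codes.size
    if n < L:
        return []
    hits = []
    # window scores via summed per-position lookups
    window = np.zeros(n - L + 1, dtype=np.int64)
    valid = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        c = codes[j : j + n - L + 1]
        bad = c < 0
        valid &= ~bad
        window += np.where(bad, 0, st.int_scores[np.clip(c, 0, 3), j])
    for off in np.flatnonzero(valid & (window >= st.threshold_int)):
        hits.append((int(off), int(window[off])))
    return hits


def scan_promoters(
    thresholds: list[ScanThreshold], promoters: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan both strands of every promoter with every calibrated motif.

    Returns ``(presence, hits)``: a genes x motifs boolean presence matrix
    (>= 1 hit on either strand) and a hit table with columns
    ``gene_id, motif_id, offset, strand, score``.  Offsets of minus-strand
    hits index the forward sequence position of the site's 5' end.
    """
    genes = list(promoters)
    presence = pd.DataFrame(
        False, index=pd.Index(genes, name="gene_id"),
        columns=[st.motif.id for st in thresholds],
    )
    hit_rows = []
    encoded = {g: _encode(s) for g, s in promoters.items()}
    for st in thresholds:
        rc = ScanThreshold(
            motif=st.motif,
            int_scores=st.int_scores[::-1, ::-1],
            threshold_int=st.threshold_int,
            granularity=st.granularity,
            pvalue=st.pvalue,
            attained_p=st.attained_p,
        )
        L = st.int_scores.shape[1]
        for g in genes:
            codes = encoded[g]
            for off, sc in _scan_one(codes, st):
                hit_rows.append(
                    {"gene_id": g, "motif_id": st.motif.id, "offset": off,
                     "strand": "+", "score": sc * st.granularity}
                )
                presence.at[g, st.motif.id] = True
            for off, sc in _scan_one(codes, rc):
                hit_rows.append(
                    {"gene_id": g, "motif_id": st.motif.id, "offset": off,
                     "strand": "-", "score": sc * st.granularity}
                )
                presence.at[g, st.motif.id] = True
    hits = pd.DataFrame(
        hit_rows, columns=["gene_id", "motif_id", "offset", "strand", "score"]
    )
    return presence, hits


# ---------------------------------------------------------------------------
# UPGMA merging of redundant motifs
# ---------------------------------------------------------------------------


def _best_offset_pcc(a: np.ndarray, b: np.ndarray, min_overlap: int = 4):
    """Best mean column-wise Pearson correlation over all alignment offsets.

    Returns (pcc, offset) where ``offset`` is the shift of b relative to a.
    """
    la, lb = a.shape[1], b.shape[1]
    best, best_off, best_ov = -1.0, 0, 0
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        a0, a1 = max(0, off), min(la, off + lb)
        if a1 - a0 < min_overlap:
            continue
        cols_a = a[:, a0:a1]
        cols_b = b[:, a0 - off : a1 - off]
        pccs = []
        for j in range(cols_a.shape[1]):
            x, y = cols_a[:, j], cols_b[:, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                pccs.append(1.0 if np.allclose(x, y) else 0.0)
            else:
                pccs.append(float(np.corrcoef(x, y)[0, 1]))
        m = float(np.mean(pccs))
        ov = a1 - a0
        # ties in mean PCC resolved toward the longer alignment
        if m > best + 1e-12 or (abs(m - best) <= 1e-12 and ov > best_ov):
            best, best_off, best_ov = m, off, ov
    return best, best_off


def _average_group(group: list[Motif]) -> Motif:
    """Position-wise average of a motif group at best pairwise offsets."""
    ref = group[0]
    la = ref.length
    offs = [0]
    for m in group[1:]:
        _, off = _best_offset_pcc(ref.pwm, m.pwm)
        offs.append(off)
    lo = min(offs)
    hi = max(off + m.length for off, m in zip(offs, group))
    total = np.zeros((4, hi - lo))
    counts = np.zeros(hi - lo)
    for off, m in zip(offs, group):
        total[:, off - lo : off - lo + m.length] += m.pwm
        counts[off - lo : off - lo + m.length] += 1
    avg = total / counts
    # trim flanks covered by a single member only when that keeps length >= 4
    core = np.flatnonzero(counts == counts.max())
    if core.size >= 4:
        avg = avg[:, core[0] : core[-1] + 1]
    name = "|".join(m.id for m in group)
    return Motif(name, avg / avg.sum(axis=0))


def merge_motifs_upgma(
    motifs: list[Motif], merge_threshold: float = 0.25, min_overlap: int = 4
) -> list[Motif]:
    """Collapse redundant PWMs by UPGMA at a correlation-distance cut.

    Pairwise distance is 1 minus the best-offset mean column PCC (distance
    1 when no alignment achieves ``min_overlap`` columns).  The average-
    linkage tree is cut at ``merge_threshold``; each resulting group is
    replaced by its position-wise average PWM.
    """
    if len(motifs) < 2:
        return list(motifs)
    n = len(motifs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pcc, _ = _best_offset_pcc(motifs[i].pwm, motifs[j].pwm, min_overlap)
            dist[i, j] = dist[j, i] = max(0.0, 1.0 - pcc)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=merge_threshold, criterion="distance")
    merged = []
    for lab in np.unique(labels):
        group = [motifs[i] for i in np.flatnonzero(labels == lab)]
        merged.append(group[0] if len(group) == 1 else _average_group(group))
    return merged


# ---------------------------------------------------------------------------
# Simple enumerative k-mer discovery (seed-motif stand-in)
# ---------------------------------------------------------------------------


def kmer_enrichment_finder(
    foreground: dict[str, str],
    background: dict[str, str],
    k: int = 6,
    alpha: float = 0.05,
    max_motifs: int = 10,
) -> list[Motif]:
    """Enumerate all k-mers and keep those over-represented in foreground.

    A deliberately simple discovery step: presence (either strand) of every
    k-mer is compared between foreground and background promoters with
    Fisher's exact test (BH-adjusted); significant k-mers are returned as
    near-consensus PWMs, most significant first.
    """
    from itertools import product

    from scipy.stats import fisher_exact
    from statsmodels.stats.multitest import multipletests

    def present(seqs: dict[str, str], kmer: str) -> int:
        rc = reverse_complement(kmer)
        return sum(1 for s in seqs.values() if kmer in s.upper() or rc in s.upper())

    n_fg, n_bg = len(foreground), len(background)
    records = []
    for kmer_t in product(ALPHABET, repeat=k):
        kmer = "".join(kmer_t)
        if reverse_complement(kmer) < kmer:
            continue  # canonical strand only
        a = present(foreground, kmer)
        if a == 0:
            continue
        c = present(background, kmer)
        _, p = fisher_exact([[a, n_fg - a], [c, n_bg - c]], "greater")
        records.append((kmer, a, c, p))
    if not records:
        return []
    df = pd.DataFrame(records, columns=["kmer", "fg", "bg", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df[df["p_adj"] < alpha].sort_values("p_adj").head(max_motifs)
    return [Motif.from_consensus(f"kmer_{r.kmer}", r.kmer) for r in df.itertuples()]
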