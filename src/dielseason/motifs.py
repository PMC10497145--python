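"""Promoter extraction, PWM scanning, and motif over-representation.

Promoters are the window from 1,500 bp upstream to 500 bp downstream of
each gene's transcription start site, oriented 5'->3' relative to
transcription.  Position frequency matrices (JASPAR or minimal MEME
format) are regularized with a small pseudo-probability and converted to
log-odds (bits) against the background composition; a promoter "contains"
a motif when at least one window on either strand scores at or above the
mapping threshold (8 bits by default).  Per-subgroup enrichment against
the background promoter universe is an exact hypergeometric test with BH
adjustment across motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.motifs import matrix as bio_matrix
from Bio.Seq import Seq
import gffutils
from pyfaidx import Fasta

from .enrich import benjamini_hochberg

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

@dataclass
class PositionWeightMatrix:
    """A motif's base-probability matrix and its log-odds form."""

    motif_id: str
    probabilities: np.ndarray                     # 4 x width, rows A,C,G,T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudo: float = 1e-3

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape[0] != 4 or p.shape[1] < 4:
            raise ValueError("PWM must be 4 x width with width >= 4")
        p = (p + self.pseudo) / (p + self.pseudo).sum(axis=0, keepdims=True)
        if np.any(np.abs(p.sum(axis=0) - 1.0) > 1e-6):
            raise ValueError("columns must sum to 1 after regularization")
        self.probabilities = p

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2(p / background) per cell, in bits."""
        return np.log2(self.probabilities / self.background[:, None])

    def _pssm(self) -> bio_matrix.PositionSpecificScoringMatrix:
        lo = self.log_odds()
        values = {b: lo[i].tolist() for i, b in enumerate(_BASES)}
        return bio_matrix.PositionSpecificScoringMatrix(_BASES, values)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probabilities.argmax(axis=0))


def load_motifs(path: str | Path, fmt: str = "jaspar",
                pseudo: float = 1e-3) -> list[PositionWeightMatrix]:
    """Read JASPAR (``jaspar``/``pfm``) or minimal MEME (``minimal``) motifs."""
    fmt = {"pfm": "jaspar", "meme": "minimal"}.get(fmt, fmt)
    with open(path) as fh:
        records = bio_motifs.parse(fh, fmt)
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in _BASES], dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        motif_id = (getattr(rec, "matrix_id", None) or rec.name
                    or f"motif{len(out) + 1}")
        out.append(PositionWeightMatrix(motif_id=motif_id,
                                        probabilities=probs, pseudo=pseudo))
    return out


def write_jaspar(pwms: list[PositionWeightMatrix], path: str | Path,
                 scale: int = 100) -> None:
    """Write PWMs as integer-count JASPAR records (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            counts = np.rint(pwm.probabilities * scale).astype(int)
            for i, b in enumerate(_BASES):
                row = " ".join(str(c) for c in counts[i])
                fh.write(f"{b}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str
    truncated: bool = False


def extract_promoters(fasta_path: str | Path, gff_path: str | Path,
                      upstream: int = 1500, downstream: int = 500
                      ) -> dict[str, PromoterRecord]:
    """Strand-oriented promoter windows around every annotated gene's TSS.

    For a + strand TSS at 1-based position s the genomic span is
    ``[s - upstream, s + downstream - 1]``; for a - strand TSS at s it is
    ``[s - downstream + 1, s + upstream]`` reverse-complemented.  Windows
    hitting a chromosome edge are truncated and flagged.
    """
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out: dict[str, PromoterRecord] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        if gene.seqid not in fa:
            warnings.warn(f"{gid}: chromosome {gene.seqid} absent from FASTA")
            continue
        chrom_len = len(fa[gene.seqid])
        if gene.strand == "-":
            tss = gene.end
            lo, hi = tss - downstream + 1, tss + upstream
        else:
            tss = gene.start
            lo, hi = tss - upstream, tss + downstream - 1
        truncated = lo < 1 or hi > chrom_len
        lo_c, hi_c = max(lo, 1), min(hi, chrom_len)
        seq = fa[gene.seqid][lo_c - 1:hi_c]            # 0-based half-open
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[gid] = PromoterRecord(gene_id=gid, sequence=str(seq).upper(),
                                  truncated=truncated)
    return out


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    offset: int          # 0-based window start within the promoter
    strand: str          # '+' forward, '-' reverse complement
    score: float         # log-odds score, bits


def scan(promoter: str, pwm: PositionWeightMatrix,
         threshold_bits: float = 8.0) -> list[MotifHit]:
    """All windows on both strands scoring >= threshold (N windows skipped)."""
    seq = promoter.upper()
    w = pwm.width
    if len(seq) < w:
        return []
    pssm = pwm._pssm()
    hits: list[MotifHit] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fwd = np.asarray(pssm.calculate(Seq(seq)), dtype=float).reshape(-1)
        rev = np.asarray(pssm.reverse_complement().calculate(Seq(seq)),
                         dtype=float).reshape(-1)
    for strand, scores in (("+", fwd), ("-", rev)):
        ok = np.flatnonzero(np.nan_to_num(scores, nan=-np.inf)
                            >= threshold_bits)
        hits.extend(MotifHit(int(i), strand, float(scores[i])) for i in ok)
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def contains_motif(promoter: str, pwm: PositionWeightMatrix,
                   threshold_bits: float = 8.0) -> bool:
    return len(scan(promoter, pwm, threshold_bits)) > 0


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def motif_enrichment(target_genes, background_genes,
                     promoters: dict[str, PromoterRecord],
                     pwms: list[PositionWeightMatrix],
                     threshold_bits: float = 8.0) -> pd.DataFrame:
    """Hypergeometric motif over-representation of targets vs background.

    ``background_genes`` is the promoter universe; targets must be a
    subset.  Motifs hitting zero promoters are skipped.
    """
    universe = [g for g in background_genes if g in promoters]
    targets = set(target_genes) & set(universe)
    if not set(target_genes) <= set(universe):
        missing = set(target_genes) - set(universe)
        warnings.warn(f"{len(missing)} target genes lack promoters; dropped")
    from scipy.stats import hypergeom

    rows = []
    for pwm in pwms:
        has = {g for g in universe
               if contains_motif(promoters[g].sequence, pwm, threshold_bits)}
        K, N, n = len(has), len(universe), len(targets)
        if K == 0:
            continue
        k = len(has & targets)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((pwm.motif_id, k, n, K, N, fold, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["motif", "k", "n", "K", "N",
                                      "fold", "p"]).set_index("motif")
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else []
    return out
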