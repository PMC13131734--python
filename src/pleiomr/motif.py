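"""Promoter PWM scanning, variant motif disruption, and motif-set enrichment.

Promoter windows span -1000/+300 bp around the transcription start site,
reflected by strand so "upstream" follows transcription direction. Motif
matches are scored as log-likelihood ratios against a background base
composition and scaled from 0 to 1 as a fraction of each motif's possible
score range; matches at scaled score >= 0.85 are retained. A variant
disrupts a motif when the reference and alternate alleles score differently
at an overlapping match and at least one allele exceeds the threshold.
Set-level enrichment of a motif in target vs background promoters uses the
one-sided hypergeometric tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G

DEFAULT_SCORE_THRESHOLD = 0.85


@dataclass
class MotifConfig:
    """Promoter-window geometry and scanning thresholds."""

    upstream: int = 1000
    downstream: int = 300
    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    enrichment_p_filter: float = 0.05


@dataclass
class Pwm:
    """Position weight matrix over {A, C, G, T}.

    ``matrix`` holds per-position base probabilities (rows sum to 1). A
    pseudocount is added before the log transform so absent bases score
    finitely; scores are log2 likelihood ratios against ``background``.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.01
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log2(p / np.asarray(self.background))

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    def scale(self, score):
        """Map raw log-odds scores onto [0, 1] over the motif's score range."""
        return (score - self.min_score) / (self.max_score - self.min_score)


def read_jaspar(path: str | Path) -> list[Pwm]:
    """Read PWMs from a JASPAR-format matrix file (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        probs = counts / counts.sum(axis=1, keepdims=True)
        out.append(Pwm(name=m.name or m.matrix_id, matrix=probs))
    return out


def hormone_receptor_pwm(name: str = "AR-like") -> Pwm:
    """A built-in steroid-hormone-receptor-like palindromic PWM.

    Models the canonical inverted-repeat half-site arrangement
    (AGAACAnnnTGTTCT) characteristic of androgen-receptor response elements;
    used as the default motif for synthetic promoter studies.
    """
    site = "AGAACATTGTGTTCT"
    strong, weak = 0.91, 0.03
    mat = np.full((len(site), 4), weak)
    for i, b in enumerate(site):
        mat[i] = weak
        mat[i, _BASE_INDEX[b]] = strong
    # spacer positions are unconstrained
    for i in (6, 7, 8):
        mat[i] = 0.25
    return Pwm(name=name, matrix=mat)


@dataclass
class MotifHit:
    """One PWM match within a sequence window."""

    sequence_id: str
    offset: int  # 0-based, on the forward strand of the scanned sequence
    strand: str
    scaled_score: float
    ref_score: float | None = None
    alt_score: float | None = None
    delta: float | None = None


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    arr = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def promoter_window(
    tss: int,
    strand: str,
    config: MotifConfig | None = None,
    contig_length: int | None = None,
) -> tuple[int, int]:
    """Promoter interval around a 1-based TSS, as 0-based half-open coordinates.

    On the + strand the window covers ``upstream`` bases before and
    ``downstream`` bases after the TSS; on the - strand the window is
    reflected so upstream still precedes the TSS in transcription direction.
    Windows reaching past the contig bounds are clipped with a warning.
    """
    cfg = config or MotifConfig()
    t0 = tss - 1
    if strand == "+":
        start, end = t0 - cfg.upstream, t0 + cfg.downstream
    elif strand == "-":
        start, end = t0 - cfg.downstream + 1, t0 + cfg.upstream + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0:
        log.warning("promoter window at tss=%d clipped at contig start", tss)
        start = 0
    if contig_length is not None and end > contig_length:
        log.warning("promoter window at tss=%d clipped at contig end", tss)
        end = contig_length
    return start, end


def _scan_scores(enc: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Raw scores at every offset; NaN where the window contains N."""
    L = lom.shape[0]
    n = len(enc) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for k in range(L):
        col = enc[k: k + n]
        bad = col < 0
        valid &= ~bad
        scores += lom[k, np.where(bad, 0, col)]
    scores[~valid] = np.nan
    return scores


def pwm_scan(
    sequence: str,
    pwm: Pwm,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    sequence_id: str = "",
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan a sequence for motif matches at or above a scaled-score threshold.

    Both strands are scanned by default; hit offsets always refer to the
    forward strand of the input. Windows containing N are skipped; a
    sequence shorter than the motif yields no hits.
    """
    enc = _encode(sequence)
    L = pwm.length
    lom = pwm.log_odds
    hits: list[MotifHit] = []

    fwd = pwm.scale(_scan_scores(enc, lom))
    for off in np.flatnonzero(~np.isnan(fwd) & (fwd >= threshold)):
        hits.append(MotifHit(sequence_id, int(off), "+", float(fwd[off])))
    if both_strands:
        rev_enc = enc[::-1]
        rc = np.where(
            rev_enc >= 0, _COMPLEMENT_IDX[np.clip(rev_enc, 0, 3)], -1
        ).astype(np.int8)
        rev = pwm.scale(_scan_scores(rc, lom))
        n = len(enc) - L + 1
        for off in np.flatnonzero(~np.isnan(rev) & (rev >= threshold)):
            hits.append(
                MotifHit(sequence_id, int(n - 1 - off), "-", float(rev[off]))
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _best_scaled_overlapping(seq: str, pwm: Pwm, pos: int) -> float:
    """Best scaled score among windows (both strands) overlapping ``pos``."""
    enc = _encode(seq)
    L = pwm.length
    lo = max(0, pos - L + 1)
    hi = min(len(seq) - L, pos)
    if hi < lo:
        return float("-inf")
    sub = enc[lo: hi + L]
    fwd = _scan_scores(sub, pwm.log_odds)
    rev_sub = sub[::-1]
    rc = np.where(rev_sub >= 0, _COMPLEMENT_IDX[np.clip(rev_sub, 0, 3)], -1).astype(
        np.int8
    )
    rev = _scan_scores(rc, pwm.log_odds)
    allscores = np.concatenate([fwd, rev])
    allscores = allscores[~np.isnan(allscores)]
    if len(allscores) == 0:
        return float("-inf")
    return float(pwm.scale(allscores.max()))


def variant_motif_break(
    ref_window: str,
    pos_in_window: int,
    ref_allele: str,
    alt_allele: str,
    pwm: Pwm,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    sequence_id: str = "",
) -> MotifHit | None:
    """Score a single-nucleotide variant's effect on overlapping motif matches.

    The best scaled score across offsets and strands overlapping the variant
    is computed for the reference and alternate sequences; the variant is
    retained when either allele reaches ``threshold``. ``delta`` is
    alt_score - ref_score (negative = disruption). Indels are skipped.
    """
    ref_allele, alt_allele = ref_allele.upper(), alt_allele.upper()
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles are identical; not a variant")
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        log.info("skipping indel %s>%s at %d", ref_allele, alt_allele, pos_in_window)
        return None
    if not (0 <= pos_in_window < len(ref_window)):
        raise ValueError("variant position outside the window")
    if ref_window[pos_in_window].upper() != ref_allele:
        raise ValueError(
            f"window base {ref_window[pos_in_window]!r} != ref allele {ref_allele!r}"
        )
    alt_window = (
        ref_window[:pos_in_window] + alt_allele + ref_window[pos_in_window + 1:]
    )
    ref_score = _best_scaled_overlapping(ref_window, pwm, pos_in_window)
    alt_score = _best_scaled_overlapping(alt_window, pwm, pos_in_window)
    if max(ref_score, alt_score) < threshold:
        return None
    return MotifHit(
        sequence_id=sequence_id,
        offset=pos_in_window,
        strand=".",
        scaled_score=max(ref_score, alt_score),
        ref_score=ref_score,
        alt_score=alt_score,
        delta=alt_score - ref_score,
    )


def motif_set_enrichment(
    target_windows: dict[str, str],
    background_windows: dict[str, str],
    pwm: Pwm,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> tuple[float, dict]:
    """Over-representation of motif-containing promoters in the target set.

    A promoter "contains" the motif when scanning yields at least one hit.
    The one-sided hypergeometric tail tests whether containing promoters are
    over-represented among targets within the target+background universe.
    Returns (p, counts) with the 2x2 table counts.
    """
    if not target_windows or not background_windows:
        raise ValueError("both promoter sets must be non-empty")

    def _contains(seqs):
        return sum(
            1 for sid, s in seqs.items() if len(pwm_scan(s, pwm, threshold, sid)) > 0
        )

    k_t = _contains(target_windows)
    k_b = _contains(background_windows)
    n_t, n_b = len(target_windows), len(background_windows)
    M, K = n_t + n_b, k_t + k_b
    p = float(hypergeom.sf(k_t - 1, M, K, n_t)) if K > 0 else 1.0
    counts = {
        "target_with_motif": k_t,
        "target_without_motif": n_t - k_t,
        "background_with_motif": k_b,
        "background_without_motif": n_b - k_b,
    }
    return p, counts


def motif_enrichment_report(
    target_windows: dict[str, str],
    background_windows: dict[str, str],
    pwms: list[Pwm],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    p_filter: float = 0.05,
):
    """Enrichment across a motif collection, filtered to p < ``p_filter``."""
    import pandas as pd

    rows = []
    for pwm in pwms:
        p, counts = motif_set_enrichment(target_windows, background_windows, pwm, threshold)
        rows.append({"motif": pwm.name, "p": p, **counts})
    table = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    return table[table["p"] < p_filter].reset_index(drop=True)
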