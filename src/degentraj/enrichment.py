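"""Promoter motif scanning and gene-set enrichment scoring.

Promoter sequences (already extracted to the -2000:+500 window around the
transcription start site, strand-aware) are scanned for transcription-factor
binding motifs given either as IUPAC consensus strings (exact degenerate
matching, both strands, N never matches) or as position-weight matrices
(log-odds score against a uniform background, hit when a window reaches a
fraction of the motif's maximum score; both strands).

Enrichment of a gene list against a background follows the published
combined-score recipe: one-sided Fisher exact p per motif, Benjamini-
Hochberg adjustment across motifs, a z-score measuring the deviation of the
motif's p-value rank from its expected rank under random gene lists of the
same size, and combined score c = -ln(p) * z (larger = stronger enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifDefinition:
    """One motif: either an IUPAC consensus or a PWM (positions × ACGT,
    probability columns)."""

    motif_id: str
    tf_name: str
    consensus: str | None = None
    pwm: tuple | None = None  # nested tuple, rows = positions

    def __post_init__(self):
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError(f"{self.motif_id}: provide exactly one of consensus / pwm")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{self.motif_id}: non-IUPAC characters {sorted(bad)}")
        else:
            arr = np.asarray(self.pwm, float)
            if arr.ndim != 2 or arr.shape[1] != 4:
                raise ValueError(f"{self.motif_id}: PWM must be positions × 4")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"{self.motif_id}: PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return len(self.consensus) if self.consensus is not None else len(self.pwm)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _consensus_matches(seq: str, consensus: str) -> bool:
    w = len(consensus)
    cons = [IUPAC[c] for c in consensus.upper()]
    for i in range(len(seq) - w + 1):
        window = seq[i:i + w]
        if all(base in allowed for base, allowed in zip(window, cons)):
            return True
    return False


def _pwm_log_odds(pwm: np.ndarray, pseudo: float = 1e-3) -> np.ndarray:
    p = np.asarray(pwm, float) + pseudo
    p = p / p.sum(axis=1, keepdims=True)
    return np.log2(p / 0.25)


def _pwm_matches(seq: str, pwm: np.ndarray, threshold_frac: float) -> bool:
    lo = _pwm_log_odds(pwm)
    w = lo.shape[0]
    thresh = threshold_frac * lo.max(axis=1).sum()
    codes = np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=int)
    n = len(codes)
    if n < w:
        return False
    for i in range(n - w + 1):
        window = codes[i:i + w]
        if (window < 0).any():  # N or unknown never matches
            continue
        if lo[np.arange(w), window].sum() >= thresh:
            return True
    return False


def scan_promoters(
    promoters: dict[str, str],
    motifs: list[MotifDefinition],
    pwm_threshold: float = 0.8,
) -> dict[str, set]:
    """Per-motif set of gene names with >= 1 match in their promoter window.

    ``promoters`` maps gene name -> sequence. Both strands are scanned.
    Sequences may contain only A/C/G/T/N (case-insensitive); anything else is
    an error naming the record. N never matches.
    """
    seqs = {}
    for name, seq in promoters.items():
        s = str(seq).upper()
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter {name!r}: invalid characters {sorted(bad)}")
        seqs[name] = s
    hits: dict[str, set] = {}
    for m in motifs:
        found = set()
        for name, s in seqs.items():
            rc = reverse_complement(s)
            if m.consensus is not None:
                if _consensus_matches(s, m.consensus) or _consensus_matches(rc, m.consensus):
                    found.add(name)
            else:
                pwm = np.asarray(m.pwm, float)
                if _pwm_matches(s, pwm, pwm_threshold) or _pwm_matches(rc, pwm, pwm_threshold):
                    found.add(name)
        hits[m.motif_id] = found
    return hits


def fisher_enrichment_p(n_overlap: int, list_size: int, n_hits: int, background_size: int) -> float:
    """One-sided (enrichment) Fisher exact p = P(X >= n_overlap) with
    X ~ Hypergeom(background_size, n_hits, list_size)."""
    return float(hypergeom.sf(n_overlap - 1, background_size, n_hits, list_size))


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def motif_enrichment(
    gene_list,
    background,
    hit_sets: dict[str, set],
    n_random: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of ``gene_list`` (⊆ background) for each motif's hit set.

    Columns mirror the standard enrichment report: overlap (numerator /
    denominator), p_value (one-sided Fisher), p_adjusted (BH across motifs),
    z_score (deviation of the observed p-value rank from its expectation over
    ``n_random`` random gene lists of the same size) and combined_score
    = -ln(p) * z. Rows are sorted by decreasing combined score.
    """
    background = list(dict.fromkeys(background))
    bset = set(background)
    gene_list = list(dict.fromkeys(gene_list))
    if not set(gene_list) <= bset:
        raise ValueError("gene_list must be a subset of background")
    N, n = len(background), len(gene_list)
    gset = set(gene_list)

    motif_ids, hits_in_bg = [], []
    for mid, hs in hit_sets.items():
        h = hs & bset
        if not h:
            continue  # motif with zero hits in background is uninformative
        motif_ids.append(mid)
        hits_in_bg.append(h)
    if not motif_ids:
        return pd.DataFrame(
            columns=["overlap", "n_hits", "p_value", "p_adjusted", "z_score", "combined_score"]
        ).rename_axis("motif")

    overlaps = np.array([len(h & gset) for h in hits_in_bg])
    Ks = np.array([len(h) for h in hits_in_bg])
    pvals = hypergeom.sf(overlaps - 1, N, Ks, n)

    # rank-deviation z: observed rank of each motif (by p) vs its rank
    # distribution over random same-size gene lists
    rng = np.random.default_rng(seed)
    member = np.zeros((len(motif_ids), N), dtype=bool)
    index_of = {g: i for i, g in enumerate(background)}
    for r, h in enumerate(hits_in_bg):
        member[r, [index_of[g] for g in h]] = True
    obs_rank = pd.Series(pvals).rank(method="average").to_numpy()
    rand_ranks = np.empty((n_random, len(motif_ids)))
    for rep in range(n_random):
        pick = rng.choice(N, size=n, replace=False)
        ov = member[:, pick].sum(axis=1)
        pv = hypergeom.sf(ov - 1, N, Ks, n)
        rand_ranks[rep] = pd.Series(pv).rank(method="average").to_numpy()
    exp_rank = rand_ranks.mean(axis=0)
    sd_rank = rand_ranks.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_rank > 0, (exp_rank - obs_rank) / sd_rank, 0.0)

    with np.errstate(divide="ignore"):
        combined = -np.log(np.maximum(pvals, 1e-300)) * z
    out = pd.DataFrame(
        {
            "overlap": overlaps,
            "n_hits": Ks,
            "p_value": pvals,
            "p_adjusted": benjamini_hochberg(pvals),
            "z_score": z,
            "combined_score": combined,
        },
        index=pd.Index(motif_ids, name="motif"),
    )
    return out.sort_values("combined_score", ascending=False, kind="stable")


def read_motifs(path: str, fmt: str = "auto") -> list[MotifDefinition]:
    """Read motifs from a MEME-minimal or JASPAR PFM file (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    if fmt == "auto":
        with open(path) as fh:
            head = fh.read(2048)
        fmt = "minimal" if "MEME version" in head else "jaspar"
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)], float)
        pwm = counts / counts.sum(axis=1, keepdims=True)
        name = (m.name or getattr(m, "base_id", None) or "motif").strip()
        mid = getattr(m, "matrix_id", None) or name
        out.append(MotifDefinition(motif_id=str(mid), tf_name=str(name),
                                   pwm=tuple(map(tuple, pwm))))
    return out
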