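"""Primer-pair design over unique SSR flanks.

One forward/reverse pair is designed per locus by exhaustive enumeration of
primer placements in the two flanks under a Primer3-style constraint box
(length 18-27 nt with optimum 20, GC 20-80 %, Tm 57-63 degC with optimum 60,
product 30-500 bp, mononucleotide runs capped at 5). Among feasible pairs the
one minimizing

    penalty = |len_f - len_opt| + |len_r - len_opt| + |Tm_f - Tm_opt| + |Tm_r - Tm_opt|

is returned (Tm weighted 1 per degC), with ties broken by smaller product and
then leftmost forward primer, so the choice is deterministic.

The melting temperature is a nearest-neighbor (unified thermodynamic
parameter) calculation at 50 mM monovalent salt and 50 nM oligo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .flank_screen import FlankedLocus
from .io_formats import revcomp

# Unified nearest-neighbor parameters: dinucleotide -> (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R = 1.987  # gas constant, cal/(K*mol)


@dataclass
class PrimerConfig:
    len_min: int = 18
    len_opt: int = 20
    len_max: int = 27
    gc_min: float = 20.0
    gc_max: float = 80.0
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    product_min: int = 30
    product_max: int = 500
    tm_method: str = "nearest-neighbor, 50 mM monovalent, 50 nM oligo"
    max_poly_x: int = 5
    monovalent_mM: float = 50.0
    oligo_nM: float = 50.0

    def __post_init__(self) -> None:
        if not (self.len_min <= self.len_opt <= self.len_max):
            raise ValueError("primer length bounds must satisfy min <= opt <= max")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("Tm bounds must satisfy min <= opt <= max")
        if not self.product_min < self.product_max:
            raise ValueError("product_min must be < product_max")


@dataclass(frozen=True)
class PrimerPair:
    locus_id: str
    fwd_seq: str
    rev_seq: str  # 5'->3', reverse-complemented relative to the template
    fwd_start: int  # reference coordinate of forward primer 5' end
    rev_end: int  # reference coordinate just past reverse primer 5' end
    product_len: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    penalty: float


def melting_temp(seq: str, cfg: PrimerConfig | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    Unified NN enthalpies/entropies with terminal AT/GC initiation terms,
    entropic salt correction (0.368 * (N-1) * ln[Na+]) and the standard
    non-self-complementary strand-concentration term (C_T / 4).
    """
    cfg = cfg or PrimerConfig()
    if len(seq) < 8:
        raise ValueError("sequence too short for NN Tm (need >= 8 nt)")
    if not set(seq) <= set("ACGT"):
        raise ValueError(f"non-ACGT character in {seq!r}")
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        h, s = _INIT_GC if term in "GC" else _INIT_AT
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    na = cfg.monovalent_mM / 1000.0
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    ct = cfg.oligo_nM * 1e-9
    tm_k = dh * 1000.0 / (ds + _R * math.log(ct / 4.0))
    return tm_k - 273.15


def gc_fraction(seq: str) -> float:
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _self_dimer(seq: str, word: int = 8) -> bool:
    """Simple screen: an 8 bp word whose reverse complement also lies in the primer."""
    words = {seq[i : i + word] for i in range(len(seq) - word + 1)}
    return any(revcomp(w) in words for w in words)


def _candidates(flank: str, cfg: PrimerConfig) -> list[tuple[float, int, int, str, float, float]]:
    """All primers satisfying the per-primer box in one flank.

    Returns tuples (penalty, offset, length, seq, tm, gc) with offset the
    primer start within the flank.
    """
    out = []
    for length in range(cfg.len_min, cfg.len_max + 1):
        for off in range(0, len(flank) - length + 1):
            s = flank[off : off + length]
            if "N" in s:
                continue
            gc = gc_fraction(s)
            if not (cfg.gc_min <= gc <= cfg.gc_max):
                continue
            if _max_run(s) > cfg.max_poly_x:
                continue
            tm = melting_temp(s, cfg)
            if not (cfg.tm_min <= tm <= cfg.tm_max):
                continue
            if _self_dimer(s):
                continue
            pen = abs(length - cfg.len_opt) + abs(tm - cfg.tm_opt)
            out.append((pen, off, length, s, tm, gc))
    return out


def design_primers(locus: FlankedLocus, cfg: PrimerConfig | None = None) -> PrimerPair | None:
    """Design the best-scoring primer pair for a unique-flank locus.

    Returns None when no placement satisfies the constraint box (e.g. flanks
    too AT-rich to reach the minimum Tm, or no product size within bounds).
    """
    cfg = cfg or PrimerConfig()
    t = locus.tract
    flank_len = len(locus.left_flank)
    fwd_cands = _candidates(locus.left_flank, cfg)
    rev_cands = [
        (pen, off, length, revcomp(s), tm, gc)
        for pen, off, length, s, tm, gc in _candidates(locus.right_flank, cfg)
    ]
    if not fwd_cands or not rev_cands:
        return None
    fwd_cands.sort(key=lambda c: (c[0], c[1]))
    rev_cands.sort(key=lambda c: (c[0], c[1]))
    tract_len = t.end - t.start
    best = None
    best_key = None
    min_rev_pen = rev_cands[0][0]
    for fpen, foff, flen, fseq, ftm, fgc in fwd_cands:
        if best_key is not None and fpen + min_rev_pen > best_key[0] + 1e-9:
            break
        for rpen, roff, rlen, rseq, rtm, rgc in rev_cands:
            total = fpen + rpen
            if best_key is not None and total > best_key[0] + 1e-9:
                break
            # product: forward primer 5' end to reverse primer 5' end
            product = (flank_len - foff) + tract_len + (roff + rlen)
            if not (cfg.product_min <= product <= cfg.product_max):
                continue
            fwd_start = t.start - flank_len + foff
            rev_end = t.end + roff + rlen
            key = (total, product, fwd_start, rev_end)
            if best_key is None or key < best_key:
                best_key = key
                best = PrimerPair(
                    locus_id=locus.locus_id,
                    fwd_seq=fseq,
                    rev_seq=rseq,
                    fwd_start=fwd_start,
                    rev_end=rev_end,
                    product_len=product,
                    fwd_tm=round(ftm, 2),
                    rev_tm=round(rtm, 2),
                    fwd_gc=round(fgc, 2),
                    rev_gc=round(rgc, 2),
                    penalty=round(total, 4),
                )
    return best


def design_all(loci: list[FlankedLocus], cfg: PrimerConfig | None = None) -> dict[str, PrimerPair]:
    """Design primers for every unique locus; loci with no feasible pair are omitted."""
    cfg = cfg or PrimerConfig()
    out: dict[str, PrimerPair] = {}
    for locus in loci:
        if not locus.unique:
            continue
        pair = design_primers(locus, cfg)
        if pair is not None:
            out[locus.locus_id] = pair
    return out
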