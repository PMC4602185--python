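"""Stalling-peak detection, USR extraction and Shine–Dalgarno filtering.

A peak is a codon whose RD/mRNA value strictly exceeds the gene's mean plus
``k_sd`` standard deviations, both computed over unmasked codons with value
> 0. The 31 codons immediately upstream of a peak (the Upstream Stalling
Region, USR) encode the amino acids occupying the ribosomal exit tunnel at
the moment of the stall.
"""
from __future__ import annotations

import logging

import numpy as np

from .core import CodingRegion, CodonProfile, InputError, Peak

logger = logging.getLogger(__name__)

DEFAULT_K_SD = 4.0
DEFAULT_TUNNEL_WINDOW = 31
CANONICAL_SD = "GGAGGU"
DEFAULT_SD_SPACINGS = (8, 9, 10, 11)
#: The literal spacing list quoted for the exclusion rule (omits 10).
LITERAL_SD_SPACINGS = (8, 9, 11)
DEFAULT_MAX_USR_COVERAGE = 0.20


def call_peaks(profile: CodonProfile, k_sd: float = DEFAULT_K_SD) -> list[Peak]:
    """Return codons with value > mean + k_sd * SD, sorted by position.

    Mean and SD (sample SD, ddof=1) are computed over unmasked, positive
    codons; with fewer than 2 such codons the SD is undefined and no peaks
    are returned (warning).
    """
    vals, mask = profile.values, profile.mask
    sel = mask & (vals > 0)
    if sel.sum() < 2:
        logger.warning("%s: <2 positive unmasked codons; no peaks called", profile.gene_id)
        return []
    mu = float(vals[sel].mean())
    sd = float(vals[sel].std(ddof=1))
    threshold = mu + k_sd * sd
    idx = np.flatnonzero(mask & (vals > threshold))
    return [Peak(profile.gene_id, int(i), float(vals[i])) for i in idx]


def extract_usr(peak: Peak, gene: CodingRegion,
                tunnel_window: int = DEFAULT_TUNNEL_WINDOW) -> Peak:
    """Attach the USR (translation of codons [peak-window, peak-1]) to a peak.

    Peaks closer than ``tunnel_window`` codons to the start get a truncated
    USR and are marked incomplete; they are excluded from enrichment
    statistics downstream.
    """
    c = peak.codon_index
    if c >= gene.n_codons:
        raise InputError(f"{gene.gene_id}: peak at codon {c} beyond gene ({gene.n_codons} codons)")
    lo = max(c - tunnel_window, 0)
    peak.usr = gene.aa_string[lo:c]
    peak.usr_complete = c >= tunnel_window
    return peak


def check_usr_coverage(gene: CodingRegion, peaks: list[Peak],
                       tunnel_window: int = DEFAULT_TUNNEL_WINDOW) -> float:
    """Fraction of the protein covered by the union of the peaks' USRs.

    Genes exceeding the 20% bound cannot be meaningfully randomized and are
    excluded from the permutation tests by the caller.
    """
    protein_length = len(gene.protein)
    if protein_length == 0:
        return 0.0
    covered = np.zeros(protein_length, dtype=bool)
    for p in peaks:
        lo = max(p.codon_index - tunnel_window, 0)
        hi = min(p.codon_index, protein_length)
        covered[lo:hi] = True
    return float(covered.sum()) / protein_length


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def filter_sd_peaks(
    peaks: list[Peak],
    gene: CodingRegion,
    canonical: str = CANONICAL_SD,
    max_mismatch: int = 1,
    spacings: tuple[int, ...] = DEFAULT_SD_SPACINGS,
) -> tuple[list[Peak], list[Peak]]:
    """Flag peaks downstream of Shine–Dalgarno-like hexamers (prokaryotes).

    For a peak whose A-site codon starts at nucleotide ``a``, the hexamer
    ending ``s`` nucleotides upstream of ``a`` (nucleotides [a-s-6, a-s-1],
    read as RNA) is compared to the canonical SD for each spacing ``s``; a
    match within ``max_mismatch`` substitutions excludes the peak. Spacings
    whose window extends before position 0 are skipped. Returns
    (retained, excluded); excluded peaks carry ``sd_flagged=True``.
    """
    rna = gene.sequence.replace("T", "U")
    canonical = canonical.upper().replace("T", "U")
    retained, excluded = [], []
    for peak in peaks:
        a = 3 * peak.codon_index
        hit = False
        for s in spacings:
            lo = a - s - 6
            if lo < 0:
                continue
            if _hamming(rna[lo:lo + 6], canonical) <= max_mismatch:
                hit = True
                break
        if hit:
            peak.sd_flagged = True
            excluded.append(peak)
        else:
            retained.append(peak)
    return retained, excluded
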