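"""tRNA adaptation index (tAI) and the rare-codon confound check.

The tAI weight of a sense codon is W = sum over decoding anticodons of
(1 - s) * tGCN, where tGCN is the tRNA gene copy number of the anticodon and
s the selective penalty of the wobble pairing class; w = W / max(W), with
zero-W codons assigned the geometric mean of the non-zero weights. The
confound check correlates (Spearman) the probability that each sense codon
occupies the P-site at peak positions with its tAI: a strong negative
correlation would mean the stalling signal is explainable by rare codons.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import CodingRegion, InputError, Peak, SENSE_CODONS

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def default_s_values() -> dict[str, float]:
    text = resources.files("stallscan").joinpath("data/s_values.yaml").read_text()
    return {k: float(v) for k, v in yaml.safe_load(text).items()}


#: wobble anticodon first base and pairing class, keyed by codon third base
_WOBBLE_RULES = {
    "T": ("G", "g_u"),
    "C": ("A", "i_c"),
    "A": ("A", "i_a"),
    "G": ("T", "u_g"),
}


@dataclass
class TAITable:
    """Relative adaptiveness w per sense codon, with its inputs."""

    w: dict[str, float]
    tgcn: dict[str, float]
    s_values: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"codon": list(self.w), "w": list(self.w.values())}).set_index("codon")


def compute_tai(tgcn: dict[str, float],
                s_values: dict[str, float] | None = None) -> TAITable:
    """Compute relative adaptiveness w for the 61 sense codons.

    ``tgcn`` maps anticodons (5'->3', DNA or RNA alphabet) to gene copy
    numbers. For each codon the Watson-Crick anticodon and the single
    wobble anticodon of its third-base class contribute (1 - s) * tGCN.
    """
    if s_values is None:
        s_values = default_s_values()
    tgcn = {k.upper().replace("U", "T"): float(v) for k, v in tgcn.items()}
    if any(v < 0 for v in tgcn.values()):
        raise InputError("negative tRNA gene copy number")
    if not any(v > 0 for v in tgcn.values()):
        raise InputError("all tRNA gene copy numbers are zero")
    if not all(0.0 <= s <= 1.0 for s in s_values.values()):
        raise InputError("s-values must lie in [0, 1]")

    W: dict[str, float] = {}
    for codon in SENSE_CODONS:
        wc_anticodon = _revcomp(codon)
        value = (1.0 - s_values.get("watson_crick", 0.0)) * tgcn.get(wc_anticodon, 0.0)
        wobble_base, pairing = _WOBBLE_RULES[codon[2]]
        wobble_anticodon = wobble_base + wc_anticodon[1:]
        value += (1.0 - s_values[pairing]) * tgcn.get(wobble_anticodon, 0.0)
        W[codon] = value

    w_max = max(W.values())
    if w_max == 0:
        raise InputError("no codon is decoded by the provided tRNA set")
    w = {c: v / w_max for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    geo_mean = float(np.exp(np.mean(np.log(nonzero))))
    w = {c: (v if v > 0 else geo_mean) for c, v in w.items()}
    return TAITable(w=w, tgcn=tgcn, s_values=dict(s_values))


def read_tgcn(path) -> dict[str, float]:
    """Read a tGCN TSV with columns (anticodon, copy_number)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def psite_occupancy(peaks: list[Peak], genes_by_id: dict[str, CodingRegion],
                    use_peak_codon: bool = False) -> dict[str, float]:
    """Probability that each sense codon occupies the P-site at peaks.

    Peak positions denote the A-site, so the P-site codon is one codon
    upstream (``use_peak_codon`` switches to the peak codon itself). Peaks
    whose P-site codon falls before the CDS start, or is a stop codon, are
    skipped.
    """
    if not peaks:
        raise InputError("psite_occupancy: no peaks")
    counts = {c: 0 for c in SENSE_CODONS}
    total = 0
    for p in peaks:
        idx = p.codon_index if use_peak_codon else p.codon_index - 1
        gene = genes_by_id[p.gene_id]
        if idx < 0 or idx >= gene.n_codons:
            continue
        codon = gene.codons[idx]
        if codon in counts:
            counts[codon] += 1
            total += 1
    if total == 0:
        raise InputError("psite_occupancy: no peaks with a valid P-site codon")
    return {c: n / total for c, n in counts.items()}


def tai_occupancy_correlation(occupancy: dict[str, float],
                              tai: TAITable) -> tuple[float, float]:
    """Spearman rho and p between P-site occupancy and tAI over 61 codons.

    Returns (nan, nan) when either vector is constant (rho undefined).
    """
    occ = np.array([occupancy.get(c, 0.0) for c in SENSE_CODONS])
    w = np.array([tai.w[c] for c in SENSE_CODONS])
    if np.all(occ == occ[0]) or np.all(w == w[0]):
        logger.warning("tai_occupancy_correlation: constant input, rho undefined")
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(occ, w)
    return float(rho), float(p)
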