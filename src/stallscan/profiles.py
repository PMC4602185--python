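"""Codon-resolution conversion, coverage filtering, normalization, aggregation.

The processing cascade mirrors the conservative treatment of ribosome
profiling data: nucleotide counts are averaged over codon triplets; the first
20 codons (initiation-biased) are excluded; sparse genes (< 40% non-zero ribo
codons) are removed; each profile is scaled by its own gene coverage and the
per-codon RD/mRNA ratio is formed; replicate datasets of one organism are
depth-normalized and averaged into an aggregate before normalization.
"""
from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .core import CodonProfile, DatasetBundle, InputError, NucleotideProfile

logger = logging.getLogger(__name__)

DEFAULT_MIN_NONZERO_FRACTION = 0.40
DEFAULT_EXCLUDE_FIRST = 20


def to_codon_resolution(p: NucleotideProfile) -> CodonProfile:
    """Average read counts over each codon triplet.

    A trailing remainder of 1–2 nucleotides is dropped with a warning.
    """
    if len(p) == 0:
        raise InputError(f"{p.gene_id}: empty profile")
    n = len(p) - len(p) % 3
    if n != len(p):
        logger.warning("%s: dropping %d trailing nucleotides not forming a codon",
                       p.gene_id, len(p) - n)
    values = p.values[:n].reshape(-1, 3).mean(axis=1)
    return CodonProfile(p.gene_id, values, p.assay)


def filter_profiles(
    bundle: DatasetBundle,
    min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION,
    exclude_first: int = DEFAULT_EXCLUDE_FIRST,
    require_mrna: bool = False,
) -> tuple[DatasetBundle, pd.DataFrame]:
    """Remove sparse genes and mask the first ``exclude_first`` codons.

    A gene is removed when the non-zero fraction of its ribo codon profile,
    computed over codons >= ``exclude_first``, is below the threshold
    (optionally also required of the mRNA profile). Survivors get codons
    0..exclude_first-1 masked invalid in every assay. Returns the filtered
    bundle and a per-gene report (gene_id, status, reason, nonzero fractions).
    """
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise InputError(f"min_nonzero_fraction {min_nonzero_fraction} outside [0, 1]")

    def _fraction(p: CodonProfile) -> float:
        body = p.values[exclude_first:]
        return float(np.mean(body > 0)) if len(body) else 0.0

    ribo_out, mrna_out, rows = {}, {}, []
    for gene_id in bundle.gene_ids:
        fr = _fraction(bundle.ribo[gene_id])
        fm = _fraction(bundle.mrna[gene_id]) if bundle.mrna is not None else np.nan
        checked = min(fr, fm) if (require_mrna and bundle.mrna is not None) else fr
        if checked < min_nonzero_fraction:
            rows.append((gene_id, "removed", "sparse_coverage", fr, fm))
            continue
        rp = bundle.ribo[gene_id].copy()
        rp.mask[:exclude_first] = False
        ribo_out[gene_id] = rp
        if bundle.mrna is not None:
            mp = bundle.mrna[gene_id].copy()
            mp.mask[:exclude_first] = False
            mrna_out[gene_id] = mp
        rows.append((gene_id, "retained", "", fr, fm))

    report = pd.DataFrame(
        rows, columns=["gene_id", "status", "reason", "ribo_nonzero_fraction",
                       "mrna_nonzero_fraction"])
    out = DatasetBundle(bundle.dataset_id, bundle.organism, bundle.domain_of_life,
                        ribo_out, mrna_out if bundle.mrna is not None else None)
    return out, report


def _coverage_scale(p: CodonProfile, exclude_zeros: bool) -> float:
    sel = p.mask & (p.values > 0) if exclude_zeros else p.mask
    if not sel.any():
        return 0.0
    return float(p.values[sel].mean())


def normalize_rd_over_mrna(
    bundle: DatasetBundle,
    ribo_only: bool = False,
    exclude_zeros_in_scaling: bool = False,
) -> DatasetBundle:
    """Scale each profile by its gene coverage and form the RD/mRNA ratio.

    "Gene coverage" is the simple mean over unmasked codons (zeros included
    unless ``exclude_zeros_in_scaling``). Codons where the scaled mRNA is 0
    are masked invalid; genes whose mRNA (or ribo) profile is entirely zero
    over unmasked codons are dropped with a warning. With ``ribo_only`` the
    mRNA normalization is skipped and the output is the coverage-scaled ribo
    profile (the non-normalized control).
    """
    rd: dict[str, CodonProfile] = {}
    for gene_id in bundle.gene_ids:
        rp = bundle.ribo[gene_id]
        s_r = _coverage_scale(rp, exclude_zeros_in_scaling)
        if s_r == 0.0:
            logger.warning("%s: ribo profile all-zero over unmasked codons; gene dropped", gene_id)
            continue
        scaled_r = rp.values / s_r
        mask = rp.mask.copy()
        if ribo_only or bundle.mrna is None:
            rd[gene_id] = CodonProfile(gene_id, scaled_r, "rd_over_mrna", mask)
            continue
        mp = bundle.mrna[gene_id]
        s_m = _coverage_scale(mp, exclude_zeros_in_scaling)
        if s_m == 0.0:
            logger.warning("%s: mRNA profile all-zero over unmasked codons; gene dropped", gene_id)
            continue
        scaled_m = mp.values / s_m
        ok = scaled_m > 0
        ratio = np.zeros_like(scaled_r)
        ratio[ok] = scaled_r[ok] / scaled_m[ok]
        mask &= ok
        rd[gene_id] = CodonProfile(gene_id, ratio, "rd_over_mrna", mask)

    return DatasetBundle(bundle.dataset_id, bundle.organism, bundle.domain_of_life,
                         {g: bundle.ribo[g] for g in rd},
                         {g: bundle.mrna[g] for g in rd} if bundle.mrna is not None else None,
                         rd_over_mrna=rd)


def aggregate_datasets(bundles: list[DatasetBundle]) -> DatasetBundle:
    """Merge replicate datasets of one organism into an aggregate.

    Step 1: each dataset's profiles (per assay) are divided by that dataset's
    total read count summed over all genes. Step 2: per gene, the
    depth-normalized profiles are averaged across the datasets containing it.
    Coverage scaling and RD/mRNA normalization are applied to the aggregate
    afterwards (``normalize_rd_over_mrna``), not here.
    """
    if not bundles:
        raise InputError("aggregate_datasets: empty bundle list")
    organism = bundles[0].organism
    domain = bundles[0].domain_of_life
    has_mrna = all(b.mrna is not None for b in bundles)

    def _aggregate_assay(assay: str) -> dict[str, CodonProfile]:
        totals = []
        for b in bundles:
            profs = b.ribo if assay == "ribo" else b.mrna
            totals.append(sum(float(p.values.sum()) for p in profs.values()))
        out: dict[str, CodonProfile] = {}
        universe = sorted({g for b in bundles
                           for g in (b.ribo if assay == "ribo" else b.mrna)})
        for gene_id in universe:
            parts = []
            for b, total in zip(bundles, totals):
                profs = b.ribo if assay == "ribo" else b.mrna
                if gene_id in profs:
                    if total == 0:
                        raise InputError(f"{b.dataset_id}: zero total read count")
                    parts.append(profs[gene_id].values / total)
            lengths = {len(v) for v in parts}
            if len(lengths) != 1:
                raise InputError(f"{gene_id}: profile lengths differ across datasets")
            out[gene_id] = CodonProfile(gene_id, np.mean(parts, axis=0), assay)
        return out

    return DatasetBundle(
        "aggregate(" + "+".join(b.dataset_id for b in bundles) + ")",
        organism, domain,
        _aggregate_assay("ribo"),
        _aggregate_assay("mrna") if has_mrna else None,
    )
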