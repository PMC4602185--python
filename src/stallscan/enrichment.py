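"""Permutation enrichment tests for amino acids in Upstream Stalling Regions.

The observed statistic for a target set of amino acids is the number of
peaks whose 31-codon USR contains at least one member. The null model
redraws peak positions uniformly (without replacement) from each gene's
eligible codons, keeping the per-gene peak count fixed; random USRs are the
31 codons upstream of each random position. Empirical p-values follow the
counting formula p = #{null >= observed} / N (ties included on both sides),
with the Benjamini–Hochberg step-up applied across the 20 per-amino-acid
enrichment p-values of a dataset.
"""
from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import (AA_INDEX, AMINO_ACIDS, CodingRegion, CodonProfile, InputError,
                   NEGATIVE_AAS, POSITIVE_AAS, Peak)
from .peaks import DEFAULT_TUNNEL_WINDOW

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOMIZATIONS = 1000


@dataclass
class NullModel:
    """Randomized-peak null: per-gene eligible positions and draw count."""

    n_randomizations: int = DEFAULT_N_RANDOMIZATIONS
    seed: int = 0
    eligible_positions: dict[str, np.ndarray] = field(default_factory=dict)


def build_eligible_positions(
    rd_profiles: dict[str, CodonProfile],
    tunnel_window: int = DEFAULT_TUNNEL_WINDOW,
) -> dict[str, np.ndarray]:
    """Unmasked codons with a complete upstream window (index >= window)."""
    eligible = {}
    for gene_id, p in rd_profiles.items():
        idx = np.flatnonzero(p.mask)
        eligible[gene_id] = idx[idx >= tunnel_window]
    return eligible


def window_presence(gene: CodingRegion,
                    tunnel_window: int = DEFAULT_TUNNEL_WINDOW) -> np.ndarray:
    """Boolean (n_codons, 20) matrix: amino acid a occurs in [p-window, p-1]."""
    aa = gene.aa_string
    onehot = np.zeros((len(aa) + 1, 20), dtype=np.int32)
    for i, ch in enumerate(aa):
        j = AA_INDEX.get(ch)
        if j is not None:
            onehot[i + 1, j] = 1
    cum = np.cumsum(onehot, axis=0)
    pos = np.arange(len(aa))
    lo = np.maximum(pos - tunnel_window, 0)
    return (cum[pos] - cum[lo]) > 0


def score_usrs(peaks: list[Peak], targets: frozenset[str] | set[str]) -> int:
    """Number of peaks whose USR contains at least one target amino acid."""
    if not peaks:
        logger.warning("score_usrs: empty peak list")
        return 0
    targets = set(targets)
    return sum(1 for p in peaks if p.usr and targets & set(p.usr))


def empirical_p(observed: float, null_scores: np.ndarray, direction: str) -> float:
    """p = #{null >= obs}/N (enriched) or #{null <= obs}/N (depleted)."""
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise InputError("empirical_p: empty null scores")
    if direction == "enriched":
        return float(np.mean(null_scores >= observed))
    if direction == "depleted":
        return float(np.mean(null_scores <= observed))
    raise InputError(f"unknown direction {direction!r}")


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone q-values)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _per_gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    # Substream keyed by gene id so results do not depend on gene order.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(gene_id.encode())]))


def sample_placements(
    null: NullModel,
    peaks_per_gene: dict[str, int],
) -> dict[str, np.ndarray]:
    """Draw ``n_randomizations`` random peak sets per gene.

    Returns, for each gene with k > 0 peaks, an (N, k) integer array of codon
    positions sampled without replacement from the gene's eligible set. Genes
    with more peaks than eligible positions are skipped with a warning.
    """
    placements: dict[str, np.ndarray] = {}
    for gene_id in sorted(peaks_per_gene):
        k = peaks_per_gene[gene_id]
        if k == 0:
            continue
        eligible = np.asarray(null.eligible_positions.get(gene_id, ()), dtype=int)
        if len(eligible) < k:
            logger.warning("%s: %d peaks but only %d eligible positions; gene skipped",
                           gene_id, k, len(eligible))
            continue
        rng = _per_gene_rng(null.seed, gene_id)
        keys = rng.random((null.n_randomizations, len(eligible)))
        if k == len(eligible):
            idx = np.broadcast_to(np.arange(k), (null.n_randomizations, k))
        else:
            idx = np.argpartition(keys, k, axis=1)[:, :k]
        placements[gene_id] = eligible[idx]
    return placements


def null_score_matrix(
    placements: dict[str, np.ndarray],
    genes_by_id: dict[str, CodingRegion],
    target_sets: list[frozenset[str]],
    tunnel_window: int = DEFAULT_TUNNEL_WINDOW,
) -> np.ndarray:
    """(N, n_targets) matrix of null scores, summed over genes."""
    n = next(iter(placements.values())).shape[0] if placements else 0
    out = np.zeros((n, len(target_sets)), dtype=np.int64)
    member_idx = [np.array(sorted(AA_INDEX[a] for a in t), dtype=int) for t in target_sets]
    for gene_id, pos in placements.items():
        pres = window_presence(genes_by_id[gene_id], tunnel_window)  # (L, 20)
        win = pres[pos]  # (N, k, 20)
        for t, midx in enumerate(member_idx):
            out[:, t] += win[:, :, midx].any(axis=2).sum(axis=1)
    return out


def null_positional_counts(
    placements: dict[str, np.ndarray],
    genes_by_id: dict[str, CodingRegion],
    tunnel_window: int = DEFAULT_TUNNEL_WINDOW,
) -> np.ndarray:
    """(N, 20, window) occupancy counts of random USRs, for positional nulls.

    Tunnel position j (1-based, P-site proximal first) of a random peak at
    codon p is the amino acid at codon p - j.
    """
    if not placements:
        raise InputError("null_positional_counts: no placements")
    n = next(iter(placements.values())).shape[0]
    counts = np.zeros(n * 20 * tunnel_window, dtype=np.int64)
    offsets = np.arange(1, tunnel_window + 1)
    for gene_id, pos in placements.items():
        aa_idx = np.array([AA_INDEX.get(ch, -1) for ch in genes_by_id[gene_id].aa_string],
                          dtype=int)
        win = aa_idx[pos[:, :, None] - offsets[None, None, :]]  # (N, k, W)
        r = np.broadcast_to(np.arange(n)[:, None, None], win.shape)
        j = np.broadcast_to(offsets[None, None, :] - 1, win.shape)
        valid = win >= 0
        flat = (r[valid] * 20 + win[valid]) * tunnel_window + j[valid]
        counts += np.bincount(flat, minlength=counts.size)
    return counts.reshape(n, 20, tunnel_window)


def permutation_test(
    genes_by_id: dict[str, CodingRegion],
    peaks: list[Peak],
    null: NullModel,
    target_sets: dict[str, frozenset[str]],
    tunnel_window: int = DEFAULT_TUNNEL_WINDOW,
    placements: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, np.ndarray]]:
    """Run the randomized-peak test for several target sets on shared draws.

    Returns (table, null_matrix, placements); the table has one row per
    target with the observed score, null moments and both one-sided
    empirical p-values.
    """
    peaks_per_gene: dict[str, int] = {}
    for p in peaks:
        peaks_per_gene[p.gene_id] = peaks_per_gene.get(p.gene_id, 0) + 1
    if placements is None:
        placements = sample_placements(null, peaks_per_gene)
    usable_genes = set(placements)
    usable_peaks = [p for p in peaks if p.gene_id in usable_genes]
    names = list(target_sets)
    sets = [frozenset(target_sets[n]) for n in names]
    null_mat = null_score_matrix(placements, genes_by_id, sets, tunnel_window)

    rows = []
    n_peaks = len(usable_peaks)
    for name, targets in zip(names, sets):
        obs = score_usrs(usable_peaks, targets) if usable_peaks else 0
        col = null_mat[:, names.index(name)]
        rows.append({
            "target": name,
            "observed_score": obs,
            "n_peaks": n_peaks,
            "observed_probability": obs / n_peaks if n_peaks else np.nan,
            "null_mean": float(col.mean()) if col.size else np.nan,
            "null_sd": float(col.std(ddof=1)) if col.size > 1 else np.nan,
            "p_enriched": empirical_p(obs, col, "enriched") if col.size else np.nan,
            "p_depleted": empirical_p(obs, col, "depleted") if col.size else np.nan,
        })
    table = pd.DataFrame(rows).set_index("target")
    return table, null_mat, placements


def _classify_row(p_enr: float, p_dep: float, alpha: float) -> str:
    if p_enr < alpha:
        return "overrepresented"
    if p_dep < alpha:
        return "underrepresented"
    return "not_significant"


def classify_amino_acids(
    genes_by_id: dict[str, CodingRegion],
    peaks: list[Peak],
    null: NullModel,
    alpha: float = 0.05,
    tunnel_window: int = DEFAULT_TUNNEL_WINDOW,
    placements: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-amino-acid three-way classification with BH-FDR annotation.

    All 20 tests share one set of null draws; BH is applied to the 20
    enrichment p-values, with pass flags at the 0.05 and 0.10 FDR levels.
    """
    targets = {a: frozenset(a) for a in AMINO_ACIDS}
    if not peaks:
        logger.warning("classify_amino_acids: no peaks; everything not_significant")
        table = pd.DataFrame(
            {"observed_score": 0, "n_peaks": 0, "observed_probability": np.nan,
             "null_mean": np.nan, "null_sd": np.nan,
             "p_enriched": np.nan, "p_depleted": np.nan},
            index=pd.Index(AMINO_ACIDS, name="target"))
        table["q_value"] = np.nan
        table["classification"] = "not_significant"
        table["fdr05"] = False
        table["fdr10"] = False
        return table
    table, _, _ = permutation_test(genes_by_id, peaks, null, targets,
                                   tunnel_window, placements)
    table["q_value"] = benjamini_hochberg(table["p_enriched"].to_numpy())
    table["classification"] = [
        _classify_row(pe, pdep, alpha)
        for pe, pdep in zip(table["p_enriched"], table["p_depleted"])]
    table["fdr05"] = table["q_value"] <= 0.05
    table["fdr10"] = table["q_value"] <= 0.10
    return table


def charged_enrichment(
    genes_by_id: dict[str, CodingRegion],
    peaks: list[Peak],
    null: NullModel,
    charge: str,
    alpha: float = 0.05,
    tunnel_window: int = DEFAULT_TUNNEL_WINDOW,
    placements: dict[str, np.ndarray] | None = None,
) -> pd.Series:
    """Composite test for the positively ({K,R,H}) or negatively ({D,E})
    charged class; a USR scores +1 if any member appears, regardless of
    which other amino acids co-occur."""
    if charge not in ("positive", "negative"):
        raise InputError(f"unknown charge class {charge!r}")
    targets = {charge: frozenset(POSITIVE_AAS if charge == "positive" else NEGATIVE_AAS)}
    table, _, _ = permutation_test(genes_by_id, peaks, null, targets,
                                   tunnel_window, placements)
    row = table.loc[charge].copy()
    row["classification"] = _classify_row(row["p_enriched"], row["p_depleted"], alpha)
    return row


def enumerate_null_scores(
    genes_by_id: dict[str, CodingRegion],
    peaks_per_gene: dict[str, int],
    eligible_positions: dict[str, np.ndarray],
    target_sets: dict[str, frozenset[str]],
    tunnel_window: int = DEFAULT_TUNNEL_WINDOW,
    max_placements: int = 1_000_000,
) -> np.ndarray:
    """Exact null distribution by exhaustive enumeration of all placements.

    Every combination of per-gene peak positions (without replacement) is
    enumerated; feasible only for tiny instances. Returns an
    (n_placements, n_targets) score matrix.
    """
    gene_ids = sorted(g for g, k in peaks_per_gene.items() if k > 0)
    combos_per_gene = []
    total = 1
    for g in gene_ids:
        elig = list(map(int, eligible_positions[g]))
        k = peaks_per_gene[g]
        combos = list(itertools.combinations(elig, k))
        combos_per_gene.append(combos)
        total *= len(combos)
        if total > max_placements:
            raise InputError(f"enumeration too large (> {max_placements} placements)")
    names = list(target_sets)
    sets = [frozenset(target_sets[n]) for n in names]
    pres = {g: window_presence(genes_by_id[g], tunnel_window) for g in gene_ids}

    scores = np.zeros((total, len(sets)), dtype=np.int64)
    member_idx = [np.array(sorted(AA_INDEX[a] for a in t), dtype=int) for t in sets]
    for row, assignment in enumerate(itertools.product(*combos_per_gene)):
        for g, positions in zip(gene_ids, assignment):
            win = pres[g][np.array(positions, dtype=int)]  # (k, 20)
            for t, midx in enumerate(member_idx):
                scores[row, t] += int(win[:, midx].any(axis=1).sum())
    return scores
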