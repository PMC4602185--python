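"""Model/Results surface tying the pipeline stages together.

``RibosomeStallingModel`` holds one dataset (CDS sequences plus paired
ribo-seq/mRNA-seq nucleotide profiles) and the analysis configuration;
``fit()`` runs codon conversion, filtering, RD/mRNA normalization, peak
calling (with the Shine–Dalgarno control for prokaryotes), the permutation
enrichment tests, and the tunnel-position analysis, returning a
``StallingResults`` with the classification tables, diagnostics and a
text ``summary()``.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (AMINO_ACIDS, CodingRegion, DatasetBundle, InputError,
                   NucleotideProfile, Peak)
from .enrichment import (NullModel, build_eligible_positions, benjamini_hochberg,
                         charged_enrichment, classify_amino_acids,
                         null_positional_counts, permutation_test,
                         sample_placements)
from .peaks import (DEFAULT_K_SD, DEFAULT_MAX_USR_COVERAGE, DEFAULT_SD_SPACINGS,
                    DEFAULT_TUNNEL_WINDOW, call_peaks, check_usr_coverage,
                    extract_usr, filter_sd_peaks)
from .profiles import (DEFAULT_EXCLUDE_FIRST, DEFAULT_MIN_NONZERO_FRACTION,
                       filter_profiles, normalize_rd_over_mrna,
                       to_codon_resolution)
from .tunnel import (PositionalMatrix, flag_extreme_positions,
                     positional_probabilities, standardize)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds and mode flags for one analysis run."""

    min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION
    exclude_first: int = DEFAULT_EXCLUDE_FIRST
    k_sd: float = DEFAULT_K_SD
    tunnel_window: int = DEFAULT_TUNNEL_WINDOW
    alpha: float = 0.05
    n_randomizations: int = 1000
    max_usr_coverage: float = DEFAULT_MAX_USR_COVERAGE
    ribo_only: bool = False
    sd_spacings: tuple[int, ...] = DEFAULT_SD_SPACINGS
    compute_positions: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_nonzero_fraction <= 1:
            raise InputError("min_nonzero_fraction outside [0, 1]")
        if not 0 < self.alpha < 1:
            raise InputError("alpha outside (0, 1)")
        if self.n_randomizations < 1 or self.tunnel_window < 1:
            raise InputError("n_randomizations and tunnel_window must be >= 1")
        self.sd_spacings = tuple(int(s) for s in self.sd_spacings)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sd_spacings"] = list(self.sd_spacings)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)


class RibosomeStallingModel:
    """Stalling-site and USR-enrichment analysis of one profiling dataset."""

    def __init__(
        self,
        genes: list[CodingRegion],
        ribo: dict[str, NucleotideProfile],
        mrna: dict[str, NucleotideProfile] | None = None,
        domain_of_life: str = "eukaryote",
        dataset_id: str = "dataset",
        organism: str = "synthetic",
        config: AnalysisConfig | None = None,
    ) -> None:
        self.genes = list(genes)
        self.genes_by_id = {g.gene_id: g for g in self.genes}
        missing = set(ribo) - set(self.genes_by_id)
        if missing:
            raise InputError(f"profiles for unknown genes: {sorted(missing)[:3]}...")
        self.ribo = ribo
        self.mrna = mrna
        self.domain_of_life = domain_of_life
        self.dataset_id = dataset_id
        self.organism = organism
        self.config = config or AnalysisConfig()

    @classmethod
    def from_directory(cls, path, **kwargs) -> "RibosomeStallingModel":
        """Load cds.fasta, ribo.wig and (optionally) mrna.wig from a directory."""
        from .io import read_cds_fasta, read_wiggle

        path = Path(path)
        genes = read_cds_fasta(path / "cds.fasta")
        ribo = read_wiggle(path / "ribo.wig", "ribo")
        mrna_path = path / "mrna.wig"
        mrna = read_wiggle(mrna_path, "mrna") if mrna_path.exists() else None
        kwargs.setdefault("dataset_id", path.name)
        return cls(genes, ribo, mrna, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "StallingResults":
        cfg = self.config
        counts: dict[str, int] = {"genes_in": len(self.ribo)}

        ribo_codon = {g: to_codon_resolution(p) for g, p in self.ribo.items()}
        mrna_codon = ({g: to_codon_resolution(p) for g, p in self.mrna.items()}
                      if self.mrna is not None else None)
        bundle = DatasetBundle(self.dataset_id, self.organism, self.domain_of_life,
                               ribo_codon, mrna_codon)
        bundle, filter_report = filter_profiles(
            bundle, cfg.min_nonzero_fraction, cfg.exclude_first)
        counts["genes_after_filter"] = len(bundle.ribo)
        bundle = normalize_rd_over_mrna(bundle, ribo_only=cfg.ribo_only)
        counts["genes_after_normalization"] = len(bundle.rd_over_mrna)

        all_peaks: list[Peak] = []
        sd_excluded: list[Peak] = []
        coverage_excluded_genes: list[str] = []
        for gene_id in sorted(bundle.rd_over_mrna):
            gene = self.genes_by_id[gene_id]
            gene_peaks = call_peaks(bundle.rd_over_mrna[gene_id], cfg.k_sd)
            gene_peaks = [extract_usr(p, gene, cfg.tunnel_window) for p in gene_peaks]
            if self.domain_of_life == "prokaryote":
                gene_peaks, excluded = filter_sd_peaks(
                    gene_peaks, gene, spacings=cfg.sd_spacings)
                sd_excluded.extend(excluded)
            if check_usr_coverage(gene, gene_peaks, cfg.tunnel_window) > cfg.max_usr_coverage:
                coverage_excluded_genes.append(gene_id)
                continue
            all_peaks.extend(gene_peaks)
        counts["peaks_called"] = len(all_peaks) + len(sd_excluded)
        counts["peaks_sd_excluded"] = len(sd_excluded)
        counts["genes_excluded_usr_coverage"] = len(coverage_excluded_genes)

        usable_peaks = [p for p in all_peaks if p.usr_complete]
        counts["peaks_usr_incomplete"] = len(all_peaks) - len(usable_peaks)
        counts["peaks_tested"] = len(usable_peaks)

        rd_for_null = {g: p for g, p in bundle.rd_over_mrna.items()
                       if g not in coverage_excluded_genes}
        null = NullModel(
            n_randomizations=cfg.n_randomizations, seed=seed,
            eligible_positions=build_eligible_positions(rd_for_null, cfg.tunnel_window))

        peaks_per_gene: dict[str, int] = {}
        for p in usable_peaks:
            peaks_per_gene[p.gene_id] = peaks_per_gene.get(p.gene_id, 0) + 1
        placements = sample_placements(null, peaks_per_gene) if usable_peaks else {}
        tested_peaks = [p for p in usable_peaks if p.gene_id in placements]
        counts["genes_randomized"] = len(placements)

        amino_acids = classify_amino_acids(
            self.genes_by_id, tested_peaks, null, cfg.alpha, cfg.tunnel_window,
            placements=placements or None)
        charge_rows = []
        if tested_peaks:
            for charge in ("positive", "negative"):
                row = charged_enrichment(self.genes_by_id, tested_peaks, null, charge,
                                         cfg.alpha, cfg.tunnel_window,
                                         placements=placements)
                row.name = charge
                charge_rows.append(row)
        charges = (pd.DataFrame(charge_rows) if charge_rows
                   else pd.DataFrame(columns=["observed_score", "n_peaks"]))

        positional = None
        if cfg.compute_positions and tested_peaks:
            positional = standardize(
                positional_probabilities(tested_peaks, cfg.tunnel_window))
            null_counts = null_positional_counts(placements, self.genes_by_id,
                                                 cfg.tunnel_window)
            positional = flag_extreme_positions(positional, null_counts, cfg.alpha)

        manifest = {
            "dataset_id": self.dataset_id,
            "organism": self.organism,
            "domain_of_life": self.domain_of_life,
            "stallscan_version": __version__,
            "seed": int(seed),
            "config": cfg.to_dict(),
            "stage_counts": counts,
        }
        return StallingResults(
            model=self, peaks=all_peaks, tested_peaks=tested_peaks,
            sd_excluded=sd_excluded, coverage_excluded_genes=coverage_excluded_genes,
            amino_acids=amino_acids, charges=charges, positional=positional,
            filter_report=filter_report, rd_over_mrna=bundle.rd_over_mrna,
            manifest=manifest)


@dataclass
class StallingResults:
    """Fit output: peaks, classification tables, positional matrix, manifest."""

    model: RibosomeStallingModel
    peaks: list[Peak]
    tested_peaks: list[Peak]
    sd_excluded: list[Peak]
    coverage_excluded_genes: list[str]
    amino_acids: pd.DataFrame
    charges: pd.DataFrame
    positional: PositionalMatrix | None
    filter_report: pd.DataFrame
    rd_over_mrna: dict
    manifest: dict

    @property
    def overrepresented(self) -> list[str]:
        t = self.amino_acids
        return sorted(t.index[t["classification"] == "overrepresented"])

    @property
    def underrepresented(self) -> list[str]:
        t = self.amino_acids
        return sorted(t.index[t["classification"] == "underrepresented"])

    def peaks_frame(self) -> pd.DataFrame:
        rows = [(p.gene_id, p.codon_index, p.value, p.usr or "",
                 int(p.usr_complete), int(p.sd_flagged))
                for p in sorted(self.peaks + self.sd_excluded,
                                key=lambda q: (q.gene_id, q.codon_index))]
        return pd.DataFrame(rows, columns=["gene_id", "codon_index", "value",
                                           "usr", "usr_complete", "sd_flagged"])

    def _fmt_p(self, p: float) -> str:
        n = self.manifest["config"]["n_randomizations"]
        return f"< {1 / n:g}" if p == 0.0 else f"{p:.4g}"

    def summary(self) -> str:
        c = self.manifest["stage_counts"]
        lines = [
            "Ribosome stalling enrichment analysis",
            "=" * 53,
            f"dataset: {self.manifest['dataset_id']}  "
            f"({self.manifest['organism']}, {self.manifest['domain_of_life']})",
            f"genes: {c['genes_in']} in, {c['genes_after_filter']} after 40% filter, "
            f"{c['genes_excluded_usr_coverage']} excluded by USR-coverage bound",
            f"peaks: {c['peaks_called']} called, {c['peaks_sd_excluded']} SD-excluded, "
            f"{c['peaks_tested']} tested (complete USR)",
            f"null: {self.manifest['config']['n_randomizations']} randomizations, "
            f"seed {self.manifest['seed']}",
            "",
            "Amino-acid classification (USR enrichment)",
            "-" * 53,
        ]
        t = self.amino_acids.copy()
        t["p_enriched"] = [self._fmt_p(p) if pd.notna(p) else "nan"
                           for p in t["p_enriched"]]
        t["p_depleted"] = [self._fmt_p(p) if pd.notna(p) else "nan"
                           for p in t["p_depleted"]]
        cols = ["observed_score", "observed_probability", "null_mean",
                "p_enriched", "p_depleted", "q_value", "classification",
                "fdr05", "fdr10"]
        lines.append(t[cols].to_string(float_format=lambda x: f"{x:.3f}"))
        if len(self.charges):
            lines += ["", "Charged-class tests", "-" * 53,
                      self.charges.to_string(float_format=lambda x: f"{x:.4f}")]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write all result tables and the run manifest to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peaks_frame().to_csv(outdir / "peaks.tsv", sep="\t", index=False)
        self.amino_acids.to_csv(outdir / "amino_acid_classification.tsv", sep="\t",
                                float_format="%.10g")
        self.charges.to_csv(outdir / "charged_enrichment.tsv", sep="\t",
                            float_format="%.10g")
        self.filter_report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        if self.positional is not None:
            self.positional.probs_frame().to_csv(
                outdir / "positional_probabilities.tsv", sep="\t", float_format="%.10g")
            self.positional.standardized_frame().to_csv(
                outdir / "positional_standardized.tsv", sep="\t", float_format="%.10g")
            self.positional.flags_frame().to_csv(
                outdir / "positional_flags.tsv", sep="\t")
        from .io import write_codon_profiles

        write_codon_profiles(self.rd_over_mrna, outdir / "rd_over_mrna.tsv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def run_all(dataset_dir, outdir, seed: int = 0,
            config: AnalysisConfig | None = None,
            domain_of_life: str = "eukaryote") -> StallingResults:
    """End-to-end run on a dataset directory; writes all outputs to ``outdir``."""
    model = RibosomeStallingModel.from_directory(
        dataset_dir, domain_of_life=domain_of_life, config=config)
    results = model.fit(seed=seed)
    results.save(outdir)
    return results
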