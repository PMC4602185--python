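"""Synthetic coding sequences and ribo-seq/mRNA-seq count profiles.

The generator emulates the statistical structure the stalling analysis
assumes: per-gene mRNA-seq counts fluctuate (negative-binomially) around a
gene-specific mean, ribo-seq counts are proportional to codon dwell times
times local mRNA abundance, and the dwell time of a codon is multiplied by
``stall_multiplier`` whenever a configured stalling amino acid occurs within
the ``tunnel_window`` codons upstream (the exit-tunnel occupancy window) —
i.e. the trigger amino acid sits 1..window codons upstream of the elevated
codon, matching the USR geometry of the analysis.

One global seed controls everything; per-gene substreams are derived from
the gene id so gene order cannot change the draws.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (CODON_TO_AA, AMINO_ACIDS, CodingRegion, InputError,
                   NucleotideProfile, SENSE_CODONS, STOP_CODONS)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


def uniform_codon_usage() -> dict[str, float]:
    return {c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS}


def rare_aa_usage(rare_aas: set[str] | frozenset[str],
                  mass_per_aa: float = 0.002) -> dict[str, float]:
    """Codon usage giving each amino acid in ``rare_aas`` a small total mass.

    The remaining probability mass is spread uniformly over the codons of the
    other amino acids. Used to plant sparse stalling triggers: rare triggers
    keep the elevated-dwell windows isolated so they stand out as peaks.
    """
    rare_aas = set(rare_aas)
    rare_codons = [c for c in SENSE_CODONS if CODON_TO_AA[c] in rare_aas]
    other_codons = [c for c in SENSE_CODONS if CODON_TO_AA[c] not in rare_aas]
    if rare_aas and not rare_codons:
        raise ConfigurationError(f"no codons for amino acids {sorted(rare_aas)}")
    total_rare = mass_per_aa * len(rare_aas)
    if not 0 <= total_rare < 1:
        raise ConfigurationError("rare amino-acid mass must leave probability for the rest")
    usage = {c: mass_per_aa / sum(CODON_TO_AA[x] == CODON_TO_AA[c] for x in rare_codons)
             for c in rare_codons}
    usage.update({c: (1 - total_rare) / len(other_codons) for c in other_codons})
    return usage


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the package's standard conditions."""

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (250, 350)  # codons, incl. start, excl. stop
    codon_usage: dict[str, float] = field(default_factory=uniform_codon_usage)
    mrna_mean_range: tuple[float, float] = (5.0, 50.0)  # reads/nt, log-uniform
    mrna_noise_dispersion: float = 0.1  # NB overdispersion (0 -> Poisson)
    base_dwell: float = 1.0
    stalling_amino_acids: frozenset[str] = frozenset()
    stall_multiplier: float = 1.0
    tunnel_window: int = 31
    reads_per_gene_scale: float = 1.0
    stop_codon: str = "TAA"
    seed: int = 0

    def __post_init__(self) -> None:
        self.stalling_amino_acids = frozenset(self.stalling_amino_acids)
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        lo, hi = self.gene_length_range
        if lo < 2 or hi < lo:
            raise ConfigurationError(f"bad gene_length_range {self.gene_length_range}")
        if set(self.codon_usage) - set(SENSE_CODONS):
            raise ConfigurationError("codon_usage contains stop or invalid codons")
        total = sum(self.codon_usage.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ConfigurationError(f"codon_usage sums to {total}, not 1")
        if any(v < 0 for v in self.codon_usage.values()):
            raise ConfigurationError("negative codon usage")
        mass_per_aa = {a: 0.0 for a in AMINO_ACIDS}
        for c, v in self.codon_usage.items():
            mass_per_aa[CODON_TO_AA[c]] += v
        degenerate = [a for a, v in mass_per_aa.items() if v == 0.0]
        if degenerate:
            raise ConfigurationError(
                f"codon_usage gives zero mass to amino acid(s) {degenerate}")
        if self.stop_codon not in STOP_CODONS:
            raise ConfigurationError(f"{self.stop_codon} is not a stop codon")
        unknown = self.stalling_amino_acids - set(AMINO_ACIDS)
        if unknown:
            raise ConfigurationError(f"unknown stalling amino acids {sorted(unknown)}")
        if self.stall_multiplier < 1.0:
            raise ConfigurationError("stall_multiplier must be >= 1")
        if self.mrna_noise_dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.mrna_mean_range[0] <= 0 or self.mrna_mean_range[1] < self.mrna_mean_range[0]:
            raise ConfigurationError(f"bad mrna_mean_range {self.mrna_mean_range}")
        if self.tunnel_window < 1:
            raise ConfigurationError("tunnel_window must be >= 1")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["mrna_mean_range"] = list(self.mrna_mean_range)
        d["stalling_amino_acids"] = sorted(self.stalling_amino_acids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "gene_length_range" in d:
            d["gene_length_range"] = tuple(d["gene_length_range"])
        if "mrna_mean_range" in d:
            d["mrna_mean_range"] = tuple(d["mrna_mean_range"])
        if "stalling_amino_acids" in d:
            d["stalling_amino_acids"] = frozenset(d["stalling_amino_acids"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Standard no-signal calibration conditions (200 genes x 300 codons)."""
    defaults = dict(n_genes=200, gene_length_range=(300, 300), seed=seed)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def make_recovery_config(planted: set[str], seed: int = 0, **overrides) -> SyntheticConfig:
    """Planted-signal benchmark conditions.

    Triggers are made rare (total codon mass 0.002 per planted amino acid)
    and the dwell elevation is placed at the single codon immediately
    downstream of each trigger (generator ``tunnel_window=1``), so every
    trigger produces one isolated peak with the trigger at the P-site
    proximal USR position. Elevating the full 31-codon window instead
    produces runs of peaks whose USRs share one trigger window; such
    pseudo-replicated peaks violate the exchangeability the randomized-peak
    null assumes and no permutation test is calibrated for them, whereas
    real extreme stalls are isolated codons.
    """
    defaults = dict(
        codon_usage=rare_aa_usage(planted, mass_per_aa=0.002),
        stalling_amino_acids=frozenset(planted),
        stall_multiplier=30.0,
        tunnel_window=1,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def _gene_rng(config: SyntheticConfig, gene_id: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        [int(config.seed) & 0x7FFFFFFF, zlib.crc32(gene_id.encode())]))


def generate_cds(config: SyntheticConfig) -> list[CodingRegion]:
    """Sample coding sequences: ATG + body codons from codon_usage + stop."""
    codons = np.array(SENSE_CODONS)
    probs = np.array([config.codon_usage.get(c, 0.0) for c in SENSE_CODONS])
    probs = probs / probs.sum()
    genes = []
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed) & 0x7FFFFFFF, zlib.crc32(b"__lengths__")]))
    lengths = rng.integers(config.gene_length_range[0],
                           config.gene_length_range[1] + 1, config.n_genes)
    for i, n_codons in enumerate(lengths):
        gene_id = f"gene_{i + 1:04d}"
        grng = _gene_rng(config, gene_id)
        body = grng.choice(codons, size=int(n_codons) - 1, p=probs)
        seq = "ATG" + "".join(body) + config.stop_codon
        genes.append(CodingRegion(gene_id, seq))
    return genes


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def dwell_times(gene: CodingRegion, config: SyntheticConfig) -> np.ndarray:
    """Per-codon dwell: base * multiplier when a stalling amino acid occurs
    within the tunnel window upstream of the codon."""
    aa = gene.aa_string
    trig = np.array([a in config.stalling_amino_acids for a in aa], dtype=np.int32)
    cum = np.concatenate([[0], np.cumsum(trig)])
    pos = np.arange(len(aa))
    lo = np.maximum(pos - config.tunnel_window, 0)
    in_window = (cum[pos] - cum[lo]) > 0
    dwell = np.full(len(aa), config.base_dwell)
    dwell[in_window] *= config.stall_multiplier
    return dwell


def simulate_profiles(
    genes: list[CodingRegion], config: SyntheticConfig
) -> tuple[dict[str, NucleotideProfile], dict[str, NucleotideProfile]]:
    """Simulate paired (ribo, mRNA) nucleotide count profiles for ``genes``."""
    if not genes:
        raise InputError("simulate_profiles: no genes")
    ribo: dict[str, NucleotideProfile] = {}
    mrna: dict[str, NucleotideProfile] = {}
    log_lo, log_hi = (math.log(config.mrna_mean_range[0]),
                      math.log(config.mrna_mean_range[1]))
    for gene in genes:
        rng = _gene_rng(config, gene.gene_id)
        n_nt = gene.n_nucleotides
        gene_mean = math.exp(rng.uniform(log_lo, log_hi))
        mrna_counts = _nb_draw(rng, np.full(n_nt, gene_mean),
                               config.mrna_noise_dispersion).astype(float)
        dwell = dwell_times(gene, config)
        mrna_codon = mrna_counts.reshape(-1, 3).mean(axis=1)
        lam = config.reads_per_gene_scale * dwell * mrna_codon / config.base_dwell
        ribo_codon = _nb_draw(rng, lam, config.mrna_noise_dispersion)
        # spread each codon's reads uniformly over its 3 nucleotides
        ribo_nt = rng.multinomial(ribo_codon, [1 / 3] * 3).reshape(-1).astype(float)
        ribo[gene.gene_id] = NucleotideProfile(gene.gene_id, ribo_nt, "ribo")
        mrna[gene.gene_id] = NucleotideProfile(gene.gene_id, mrna_counts, "mrna")
    return ribo, mrna


def ground_truth(config: SyntheticConfig,
                 genes: list[CodingRegion] | None = None) -> dict:
    """The planted signal, for test harnesses: stalling set, multiplier,
    window, and (if genes are given) per-gene trigger codon positions."""
    truth = {
        "stalling_amino_acids": sorted(config.stalling_amino_acids),
        "stall_multiplier": config.stall_multiplier,
        "tunnel_window": config.tunnel_window,
    }
    if genes is not None:
        truth["trigger_positions"] = {
            g.gene_id: [i for i, a in enumerate(g.aa_string)
                        if a in config.stalling_amino_acids]
            for g in genes}
    return truth


def write_dataset(config: SyntheticConfig, outdir) -> dict:
    """Generate and write a complete dataset (FASTA, wiggles, truth, config)."""
    from .io import write_cds_fasta, write_wiggle  # local import avoids a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = generate_cds(config)
    ribo, mrna = simulate_profiles(genes, config)
    write_cds_fasta(genes, outdir / "cds.fasta")
    write_wiggle(ribo, outdir / "ribo.wig", track_name="ribo")
    write_wiggle(mrna, outdir / "mrna.wig", track_name="mrna")
    truth = ground_truth(config, genes)
    rows = [(g.gene_id,
             ",".join(map(str, truth["trigger_positions"][g.gene_id])),
             "".join(truth["stalling_amino_acids"]))
            for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "trigger_codons", "stalling_set"]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")
    return truth
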