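"""Simulation and pipeline configuration.

The simulation defaults define the study conditions the synthetic cohort
emulates: three donors, five type I IFN treatments plus mock with a fixed
potency ordering (IFN-beta strongest, IFN-alpha1 weakest), a quarter of
coding genes forming the IFN-stimulated programme, and five PBMC-like cell
types sharing a small universal ("core") programme.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .errors import ConfigError

DEFAULT_TREATMENTS = ("mock", "ifna1", "ifna2a", "ifna10", "ifnb", "ifno")

#: Treatment potency as a multiplier on the true log2 fold change.  Mock is 0
#: by definition; IFN-beta is the most potent subtype and IFN-alpha1 the
#: weakest, mirroring the ordering of response magnitudes across subtypes.
DEFAULT_POTENCY = {
    "mock": 0.0,
    "ifna1": 0.5,
    "ifna2a": 0.6,
    "ifna10": 0.7,
    "ifno": 0.85,
    "ifnb": 1.0,
}

DEFAULT_CELL_TYPES = ("cMono", "ncMono", "CD4T", "CD8T", "NK")


def _check_frac(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Every random draw derives from ``seed`` through named sub-streams, so an
    identical config yields byte-identical artifacts.
    """

    seed: int = 0

    # annotation / genome
    n_coding_genes: int = 800
    n_noncoding_genes: int = 200
    chrom_name: str = "chrSim"
    chrom_length: int = 8_000_000
    gene_length: int = 1500
    nc_gene_length: int = 800
    gene_spacing: int = 2000
    pls_frac: float = 0.7          # transcripts with a PLS near the TSS
    high_conf_frac: float = 0.6    # transcripts flagged high-confidence

    # treatments / effects
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    potency: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_POTENCY))
    n_donors: int = 3
    frac_isg: float = 0.25
    effect_log2fc: float = 2.5     # mean true log2FC of an ISG at potency 1
    de_noise_sd: float = 0.25      # SD of observed log2FC around truth

    # motif library
    n_decoy_pwms: int = 8

    # bulk abundance
    baseline_tpm_median: float = 30.0
    baseline_tpm_sigma: float = 1.0   # log-scale SD of baseline TPM
    tpm_noise_sigma: float = 0.10     # per-sample log-scale TPM noise
    library_size: float = 2e7
    library_size_sigma: float = 0.2
    nb_dispersion: float = 0.05

    # single cell
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_cells_per_sample: int = 400
    frac_core: float = 0.05        # fraction of ISGs induced in all cell types
    frac_heterogeneous: float = 0.10
    het_responder_frac: float = 0.5
    sc_library_size: float = 3000.0
    sc_library_sigma: float = 0.3
    isg_weight_boost: float = 2.5  # baseline expression multiplier for ISGs

    # ncRNA pairing
    frac_divergent_pairs: float = 0.15
    frac_antisense_pairs: float = 0.15
    frac_anticorrelated: float = 0.33

    def __post_init__(self):
        for name in ("n_coding_genes", "n_noncoding_genes", "chrom_length",
                     "gene_length", "nc_gene_length", "n_donors",
                     "n_cells_per_sample"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_decoy_pwms < 1:
            raise ConfigError("n_decoy_pwms must be >= 1")
        for name in ("pls_frac", "high_conf_frac", "frac_isg", "frac_core",
                     "frac_heterogeneous", "het_responder_frac",
                     "frac_divergent_pairs", "frac_antisense_pairs",
                     "frac_anticorrelated"):
            _check_frac(name, getattr(self, name))
        self.treatments = tuple(self.treatments)
        self.cell_types = tuple(self.cell_types)
        if "mock" not in self.treatments:
            raise ConfigError("treatments must include 'mock'")
        missing = [t for t in self.treatments if t not in self.potency]
        if missing:
            raise ConfigError(f"potency missing for treatments: {missing}")
        if self.potency["mock"] != 0.0:
            raise ConfigError("potency['mock'] must be 0")
        for t, p in self.potency.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"potency[{t!r}] must be in [0, 1]")
        nonmock = [t for t in self.treatments if t != "mock"]
        if nonmock and max(self.potency[t] for t in nonmock) > 0:
            strongest = max(nonmock, key=lambda t: self.potency[t])
            if "ifnb" in self.potency and self.potency.get("ifnb", 0) > 0 \
                    and self.potency[strongest] > self.potency.get("ifnb", 0):
                raise ConfigError("ifnb must have the largest potency")
        if self.frac_divergent_pairs + self.frac_antisense_pairs > 1.0 + 1e-12:
            raise ConfigError(
                "frac_divergent_pairs + frac_antisense_pairs must be <= 1")

    @property
    def non_mock_treatments(self) -> tuple[str, ...]:
        return tuple(t for t in self.treatments if t != "mock")

    @property
    def samples(self) -> tuple[str, ...]:
        """Bulk sample ids, 'donor{d}_{treatment}'."""
        return tuple(
            f"donor{d}_{t}"
            for t in self.treatments
            for d in range(1, self.n_donors + 1)
        )

    def null(self) -> "SimulationConfig":
        """Copy of this config with every potency set to zero (global null)."""
        cfg = self.copy()
        cfg.potency = {t: 0.0 for t in cfg.potency}
        return cfg

    def copy(self, **overrides) -> "SimulationConfig":
        data = asdict(self)
        data["potency"] = dict(self.potency)
        data.update(overrides)
        return SimulationConfig(**data)

    def required_length(self) -> int:
        """Chromosome length needed to place all genes without collisions."""
        n_units = self.n_coding_genes + self.n_noncoding_genes
        unit = self.gene_length + self.nc_gene_length + 1000 + self.gene_spacing
        return 1000 + n_units * unit + 1000


@dataclass
class Thresholds:
    """Analysis thresholds; defaults follow the published procedure."""

    max_gap: int = 500            # bp between a PLS and a TSS
    promoter_length: int = 350    # bp, uniform promoter size
    hi: float = 2.0               # motif z-score for "likely regulated"
    lo: float = -1.0              # motif z-score for "likely unregulated"
    min_tpm: float = 10.0         # robust-expression median TPM
    padj_max: float = 0.05
    min_abs_log2fc: float = 0.585  # |log2FC| >= log2(1.5)
    min_pct: float = 0.10         # single-cell detection fraction
    logfc_threshold: float = 0.25  # single-cell pre-filter on |log2FC|
    min_avg_cells: float = 50.0   # eligibility: average cells per sample
    min_reads: int = 20           # bulk robust-expression count floor
    sc_min_fold: float = 1.5      # single-cell induction threshold (fold)

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ConfigError("hi threshold must exceed lo threshold")
        if not 0 <= self.padj_max <= 1:
            raise ConfigError("padj_max must be in [0, 1]")
        if self.promoter_length <= 0 or self.max_gap < 0:
            raise ConfigError("invalid promoter geometry thresholds")
        _check_frac("min_pct", self.min_pct)


def ordered_potencies(config: SimulationConfig) -> list[tuple[str, float]]:
    return sorted(config.potency.items(), key=lambda kv: kv[1])
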