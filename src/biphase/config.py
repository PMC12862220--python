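"""Shared constants, configuration objects and validation.

Conventions used throughout the package:

* four epigenomic channels, always in the order
  ``(ATAC, H3K4me3, H3K27ac, H3K27me3)``;
* two developmental stages by default, ``("larva", "adult")``, contrasting the
  D-shape larva with the adult mantle;
* genome coordinates are 0-based, half-open everywhere internally (BED native;
  GFF3 converted on write);
* one root seed per run, with named child streams per generator so adding a
  generator does not perturb the draws of the others.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MARKS: tuple[str, ...] = ("ATAC", "H3K4me3", "H3K27ac", "H3K27me3")
N_MARKS = len(MARKS)
STAGES: tuple[str, str] = ("larva", "adult")

#: chromatin-state categories, listed in collapse/assignment precedence order
CATEGORIES: tuple[str, ...] = (
    "Pois", "Act_promoter", "Act_enhancer", "Rep", "ATAC", "Qui",
)
ACTIVE_OR_POISED = frozenset({"Pois", "Act_promoter", "Act_enhancer"})

DEFAULT_BIN_BP = 200
DEFAULT_HMM_STATES = 8
DEFAULT_PROMOTER = (-2000, 500)     # relative to TSS, transcription-oriented
DEFAULT_WINDOW_UP = 5000            # gene window = [TSS - 5 kb, TES]
DEFAULT_DISTAL_MAX = 100_000
DEFAULT_TPM_MIN = 1.0
DEFAULT_DE_FDR = 0.05
DEFAULT_DE_LFC = 1.0
DEFAULT_PEAK_LFC = 0.0
DEFAULT_EDGE_QUANTILE = 0.75
DEFAULT_N_BOOT = 1000
DEFAULT_K_CLUSTERS = 10


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Named child random stream derived from one root seed.

    The stream key is a CRC32 of the stream name, so streams are stable across
    runs and independent of the order generators are invoked in.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())]))


def _default_emission() -> np.ndarray:
    # 8 states x (ATAC, H3K4me3, H3K27ac, H3K27me3); rows chosen so the
    # 0.5-threshold presence profiles cover all six categories
    return np.array([
        [0.95, 0.90, 0.85, 0.02],   # active promoter
        [0.90, 0.05, 0.85, 0.02],   # active enhancer
        [0.30, 0.80, 0.05, 0.85],   # poised / bivalent
        [0.05, 0.02, 0.02, 0.90],   # repressed, strong
        [0.02, 0.02, 0.02, 0.60],   # repressed, weak
        [0.85, 0.05, 0.05, 0.05],   # accessible island
        [0.02, 0.02, 0.02, 0.02],   # quiescent
        [0.10, 0.05, 0.05, 0.10],   # low signal -> quiescent
    ])


def _default_transition(k: int = 8, stickiness: float = 0.9) -> np.ndarray:
    """Sticky chain whose stationary distribution is dominated by quiescence.

    Real genomes are mostly quiescent; mark coverage around 10–20%% keeps the
    Poisson-background binarization meaningful (signal bins far above the
    genome-wide mean).  A = s·I + (1−s)·1wᵀ has stationary distribution w.
    """
    w = np.array([0.04, 0.04, 0.04, 0.06, 0.06, 0.06, 0.50, 0.20])
    if k != w.size:
        w = np.full(k, 1.0 / k)
    return stickiness * np.eye(k) + (1.0 - stickiness) * np.tile(w, (k, 1))


@dataclass
class SyntheticConfig:
    """Parameters of the planted-truth synthetic data generator.

    Defaults define the study conditions the pipeline is exercised under:
    200-bp bins, 8 chromatin states over 4 marks, two stages with 3 RNA-seq
    replicates each, negative-binomial expression with planted fold changes,
    a 20-TF / 100-true-edge network with 400 decoy motif sites, 24 paralog
    pairs (8 per divergence pattern) and a 29-ortholog, 6-stage species panel.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length_bp: int = 800_000
    bin_size_bp: int = DEFAULT_BIN_BP
    n_genes: int = 240
    n_tfs: int = 20
    n_states: int = DEFAULT_HMM_STATES
    state_emission_probs: np.ndarray = field(default_factory=_default_emission)
    state_transition_probs: np.ndarray = field(default_factory=_default_transition)
    signal_rates: tuple[float, float] = (0.3, 10.0)     # (lambda0, lambda1) per 200-bp bin
    # expression
    n_replicates: int = 3
    expr_mean_log: float = np.log(200.0)
    expr_mean_sd: float = 1.0
    expr_dispersion: float = 0.05
    n_deg: int = 60                                      # planted enriched genes
    deg_lfc_range: tuple[float, float] = (2.0, 4.0)
    linked_fraction: float = 0.8                         # enriched genes with planted mark change
    mark_fold: float = 6.0                               # active-mark rate multiplier in linked windows
    gene_length_range: tuple[int, int] = (2_000, 4_000)
    eff_length_range: tuple[int, int] = (500, 3_000)
    # network
    n_true_edges: int = 100
    n_decoy_sites: int = 400
    peak_halfwidth_bp: int = 300
    peak_atac_fold: float = 30.0
    peak_k27ac_fold: float = 30.0
    hires_bin_bp: int = 10
    hires_background_rate: float = 0.2                   # per 10-bp bin
    hires_peak_rate: float = 5.0
    footprint_center_rate: float = 0.5
    # paralogs
    paralog_patterns: dict = field(default_factory=lambda: {
        "no_divergence": 8, "one_sided": 8, "both_sided": 8,
    })
    # ortholog panel
    panel_species: tuple[str, ...] = ("cnippona", "cgigas", "pfucata", "pyessoensis", "aamphitrite")
    panel_stages: tuple[str, ...] = ("trochophore", "D-shape", "umbo", "pediveliger", "spat", "adult")
    panel_reference_species: str = "cnippona"
    panel_reference_stage: str = "D-shape"
    n_orthologs: int = 29
    panel_noise_small: float = 0.1
    panel_noise_large: float = 1.0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.state_emission_probs = np.asarray(self.state_emission_probs, float)
        self.state_transition_probs = np.asarray(self.state_transition_probs, float)
        for name in ("signal_rates", "deg_lfc_range", "gene_length_range",
                     "eff_length_range", "panel_species", "panel_stages", "stages"):
            val = getattr(self, name)
            if isinstance(val, list):
                setattr(self, name, tuple(val))

    def validate(self) -> None:
        e = np.asarray(self.state_emission_probs, float)
        a = np.asarray(self.state_transition_probs, float)
        if e.shape != (self.n_states, N_MARKS):
            raise ValueError(f"emission matrix must be {self.n_states}x{N_MARKS}, got {e.shape}")
        if np.any(e < 0) or np.any(e > 1):
            raise ValueError("emission probabilities must lie in [0, 1]")
        if a.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape mismatch")
        if np.any(a < 0) or not np.allclose(a.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if self.chrom_length_bp % self.bin_size_bp != 0:
            raise ValueError("bin_size_bp must divide chrom_length_bp")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per stage")
        if self.expr_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.n_tfs < 1 or self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must be in [1, n_genes]")
        if self.panel_noise_small < 0 or self.panel_noise_large < 0:
            raise ValueError("panel noise scales must be non-negative")
        n_paired = 2 * sum(self.paralog_patterns.values())
        if n_paired > self.n_genes:
            raise ValueError("requested paralog pairs exceed available genes")

    @property
    def n_bins_per_chrom(self) -> int:
        return self.chrom_length_bp // self.bin_size_bp

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class PipelineConfig:
    """End-to-end run configuration; thresholds default to the published values."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, str] = STAGES
    tpm_min: float = DEFAULT_TPM_MIN
    de_fdr: float = DEFAULT_DE_FDR
    de_lfc: float = DEFAULT_DE_LFC
    peak_lfc: float = DEFAULT_PEAK_LFC
    hmm_k: int = DEFAULT_HMM_STATES
    bin: int = DEFAULT_BIN_BP
    window_up: int = DEFAULT_WINDOW_UP
    promoter: tuple[int, int] = DEFAULT_PROMOTER
    distal_max: int = DEFAULT_DISTAL_MAX
    edge_quantile: float = DEFAULT_EDGE_QUANTILE
    n_boot: int = DEFAULT_N_BOOT
    k_clusters: int = DEFAULT_K_CLUSTERS
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    _KNOWN = None  # populated below

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
            syn_unknown = set(d["synthetic"]) - syn_known
            if syn_unknown:
                raise ValueError(f"unknown synthetic config keys: {sorted(syn_unknown)}")
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        for tup_key in ("stages", "promoter"):
            if tup_key in d and isinstance(d[tup_key], list):
                d[tup_key] = tuple(d[tup_key])
        return cls(**d)

    def to_dict(self) -> dict:
        def _plain(v):
            if isinstance(v, np.ndarray):
                return _plain(v.tolist())
            if isinstance(v, (tuple, list)):
                return [_plain(x) for x in v]
            if isinstance(v, dict):
                return {k: _plain(x) for k, x in v.items()}
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            return v

        return _plain(dataclasses.asdict(self))
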