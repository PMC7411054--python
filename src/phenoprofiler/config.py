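"""Screen configuration for the synthetic generator and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

CHANNELS = ("BFP", "GFP", "RFP")

#: Layout of a full 384-well screening plate: 28 vehicle (DMSO) control wells
#: and 280 compound-treated sample wells; the remaining 76 wells are unused.
CONTROL_WELLS_PER_PLATE = 28
SAMPLE_WELLS_PER_PLATE = 280


class ConfigurationError(ValueError):
    """Raised when a screen configuration is internally inconsistent."""


@dataclass
class ScreenConfig:
    """Parameters of a simulated compound screen.

    The layout parameters (concentrations, replicates, batches, control and
    sample wells per plate) default to the screening design the analysis
    assumes: each treatment is a compound at one of four concentrations,
    screened in two technical replicates in each of two imaging batches,
    i.e. four replicate wells per treatment, on 384-well plates carrying 28
    DMSO control wells and 280 sample wells.

    The generative parameters (effect sizes, nuisance SDs, cell counts)
    control the planted ground truth; see ``docs/methods.md`` for how each
    maps onto the statistical structure the downstream stages rely on.
    """

    # --- library composition -------------------------------------------------
    n_compounds: int = 60
    n_moas: int = 8
    #: number of member compounds per main MoA; compounds beyond the sum get
    #: singleton MoA descriptors of their own (small-MoA tail of real libraries)
    moa_size_distribution: Sequence[int] = field(default_factory=lambda: [5] * 8)
    #: fraction of compounds carrying a second MoA descriptor (multi-target
    #: compounds, e.g. promiscuous kinase inhibitors)
    frac_multi_moa: float = 0.18
    #: number of main MoAs whose member compounds get independent random effect
    #: directions instead of a shared one (phenotypically incoherent MoAs)
    n_incoherent_moas: int = 2

    # --- screen layout -------------------------------------------------------
    concentrations: Sequence[float] = (0.3, 1.0, 3.0, 9.0)  # µM
    n_tech_replicates: int = 2
    n_batches: int = 2

    # --- feature structure ---------------------------------------------------
    n_features: int = 96  # raw per-cell features -> 2*n+1 well descriptors
    n_redundant_blocks: int = 8
    redundant_block_size: int = 3
    n_noise_features: int = 24

    # --- effect model --------------------------------------------------------
    #: per-feature effect magnitude at saturating concentration, in units of
    #: the well-level control SD (RMS over informative features)
    effect_size_active: float = 3.0
    #: fraction of compounds outside the main MoAs that are phenotypically
    #: active; main-MoA members are always active so planted MoAs are testable
    frac_active_compounds: float = 0.53
    #: lognormal sigma of the per-compound EC50 spread (median EC50 1 µM)
    ec50_log_sigma: float = 0.8
    ec50_median_uM: float = 1.0
    hill_coefficient: float = 2.0
    #: lognormal sigma of the per-compound potency (magnitude) jitter
    magnitude_log_sigma: float = 0.25

    # --- nuisance model ------------------------------------------------------
    plate_effect_sd: float = 0.3
    batch_effect_sd: float = 0.3
    cell_noise_sd: float = 1.0
    #: SD of the additive noise on redundant features, as a fraction of
    #: cell_noise_sd (keeps |r| with the parent feature >= 0.9)
    redundant_noise_frac: float = 0.3

    # --- cells ---------------------------------------------------------------
    cells_per_well_mean: float = 200.0
    #: negative-binomial dispersion (size) parameter; larger = less dispersed
    cells_per_well_size: float = 10.0
    frac_dead: float = 0.05
    frac_missegmented: float = 0.05
    #: additive shift of dead / mis-segmented cell features (QC separability)
    dead_shift: float = 3.0

    cell_line: str = "CL1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_multi_moa", "frac_active_compounds", "frac_dead", "frac_missegmented"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} not in [0, 1]")
        for name in ("plate_effect_sd", "batch_effect_sd", "cell_noise_sd", "effect_size_active"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        conc = list(self.concentrations)
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ConfigurationError("concentrations must be strictly increasing")
        if sum(self.moa_size_distribution) > self.n_compounds:
            raise ConfigurationError(
                "moa_size_distribution sums to more compounds than n_compounds"
            )
        if len(self.moa_size_distribution) != self.n_moas:
            raise ConfigurationError("moa_size_distribution length must equal n_moas")
        if self.n_incoherent_moas > self.n_moas:
            raise ConfigurationError("n_incoherent_moas exceeds n_moas")
        n_red = self.n_redundant_blocks * self.redundant_block_size
        if n_red + self.n_noise_features >= self.n_features:
            raise ConfigurationError(
                "redundant + noise features leave no informative features"
            )
        if self.frac_dead + self.frac_missegmented >= 1.0:
            raise ConfigurationError("frac_dead + frac_missegmented must be < 1")

    # derived sizes ------------------------------------------------------------
    @property
    def n_redundant_features(self) -> int:
        return self.n_redundant_blocks * self.redundant_block_size

    @property
    def n_informative_features(self) -> int:
        return self.n_features - self.n_redundant_features - self.n_noise_features

    @property
    def n_treatments(self) -> int:
        return self.n_compounds * len(self.concentrations)

    @property
    def wells_per_treatment(self) -> int:
        return self.n_tech_replicates * self.n_batches

    @property
    def expected_live_cells(self) -> float:
        return self.cells_per_well_mean * (1.0 - self.frac_dead - self.frac_missegmented)

    @property
    def well_level_sd(self) -> float:
        """Approximate SD of a well-mean descriptor in control wells.

        Plate and batch offsets are removed by the control normalization, so
        the residual well-to-well spread of a mean descriptor is the per-cell
        noise shrunk by averaging over live cells.
        """
        return self.cell_noise_sd / max(self.expected_live_cells, 1.0) ** 0.5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["moa_size_distribution"] = list(self.moa_size_distribution)
        d["concentrations"] = list(self.concentrations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        return cls(**d)
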