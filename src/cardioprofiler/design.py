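"""Study design: compound panel, organelle feature space, simulation layout.

The default design emulates a 17-compound cardiotoxicity screen in
hiPSC-derived cardiomyocytes: each compound is tested over a 7-point
semi-logarithmic concentration range spanning its clinical exposure window,
in ≥3 cell lines with ≥6 replicate wells per condition, read out by
high-content imaging (205 morphological features over 10 organelle
compartments) and by 8-electrode multi-electrode-array (MEA) recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CompoundSpec",
    "EphysEffect",
    "StudyDesign",
    "ORGANELLE_BLOCK_SIZES",
    "CYTOPLASM_AREA",
    "TOXICITY_GROUPS",
    "build_feature_space",
    "default_compound_panel",
    "default_study_design",
    "semilog_series",
]

#: Admissible clinical toxicity groups (FDA-label categories).
TOXICITY_GROUPS = ("arrhythmia", "ischemia", "none", "structural")

#: Features per organelle compartment; sums to 205.
ORGANELLE_BLOCK_SIZES: dict[str, int] = {
    "nuclei": 25,
    "dna_damage": 18,
    "nucleoli": 20,
    "sarcomere": 22,
    "gap_junctions": 20,
    "mitochondria": 25,
    "lysosomes": 20,
    "peroxisomes": 18,
    "golgi": 18,
    "er": 19,
}

#: Name of the designated cytoplasmic-area feature (µm²), the basis of
#: per-cell outlier filtering. It lives in the sarcomere (cytoplasm) block.
CYTOPLASM_AREA = "cytoplasm_area"

# Acquisition-settings columns that imaging exports carry along; exactly
# constant by construction and expected to be removed by the NZV filter.
CONSTANT_FEATURES = ("golgi_channel_gain", "er_channel_gain")

_STATS = ("area", "intensity", "count", "texture")


def semilog_series(low: float, high: float, n: int = 7) -> tuple[float, ...]:
    """n-point semi-logarithmic concentration series from `low` to `high` µM."""
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    return tuple(np.logspace(np.log10(low), np.log10(high), n))


@dataclass(frozen=True)
class EphysEffect:
    """Electrophysiological dose-response parameters of one compound.

    bpm_shift
        Fractional change in beat rate at maximal effect (+ = faster).
    bri_inflation
        Additive inflation of the across-electrode beat-period CV at maximal
        effect (e.g. 0.10 plants a 10% beat-rate irregularity).
    fpd_shift
        Fractional change of field potential duration at maximal effect.
    quiescence_dose
        Concentration (µM) at and above which wells stop beating; None if
        the compound never silences the monolayer in the tested range.
    """

    bpm_shift: float = 0.0
    bri_inflation: float = 0.0
    fpd_shift: float = 0.0
    quiescence_dose: float | None = None


@dataclass(frozen=True)
class CompoundSpec:
    """One compound of the screening panel.

    mechanism_profile maps organelle block → maximal log-fold change of that
    block's features (sign = direction). ec50 is the concentration of
    half-maximal morphological effect (µM); viability_effect the maximal
    fractional cell loss at the top dose; mechanism_cluster the planted
    morphology class used by recovery experiments.
    """

    name: str
    concentrations: tuple[float, ...]
    toxicity_group: str
    mechanism_profile: Mapping[str, float] = field(default_factory=dict)
    ec50: float = 1.0
    hill: float = 2.0
    viability_effect: float = 0.0
    viability_ec50: float | None = None
    ephys: EphysEffect = field(default_factory=EphysEffect)
    mechanism_cluster: int = 2

    def __post_init__(self) -> None:
        if self.toxicity_group not in TOXICITY_GROUPS:
            raise ValueError(
                f"{self.name}: toxicity_group {self.toxicity_group!r} not in "
                f"{TOXICITY_GROUPS}"
            )
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 1 or np.any(np.diff(conc) <= 0) or np.any(conc <= 0):
            raise ValueError(f"{self.name}: concentrations must be positive, strictly increasing")
        if not 0.0 <= self.viability_effect <= 1.0:
            raise ValueError(f"{self.name}: viability_effect must lie in [0, 1]")
        unknown = set(self.mechanism_profile) - set(ORGANELLE_BLOCK_SIZES)
        if unknown:
            raise ValueError(f"{self.name}: unknown organelle blocks {sorted(unknown)}")


def build_feature_space(
    block_sizes: Mapping[str, int] | None = None,
) -> tuple[list[str], dict[str, list[int]]]:
    """Return (feature_names, organelle block → feature index list).

    The blocks partition the feature indices exactly. The sarcomere block's
    first feature is the designated cytoplasmic area; two acquisition-gain
    columns (exactly constant in generated data) sit in the golgi/er blocks.
    """
    sizes = dict(block_sizes or ORGANELLE_BLOCK_SIZES)
    names: list[str] = []
    blocks: dict[str, list[int]] = {}
    for block, size in sizes.items():
        idx = []
        for i in range(size):
            if block == "sarcomere" and i == 0:
                name = CYTOPLASM_AREA
            elif block == "golgi" and i == size - 1:
                name = "golgi_channel_gain"
            elif block == "er" and i == size - 1:
                name = "er_channel_gain"
            else:
                name = f"{block}_{_STATS[i % len(_STATS)]}_{i:02d}"
            idx.append(len(names))
            names.append(name)
        blocks[block] = idx
    return names, blocks


@dataclass(frozen=True)
class StudyDesign:
    """Full simulation layout for one in-silico screen."""

    compounds: tuple[CompoundSpec, ...]
    lines: tuple[str, ...] = ("NcyteCM1", "NcyteCM2", "NCRM5")
    n_replicates: int = 6
    cells_per_well: int = 2000
    n_features: int = 205
    organelle_blocks: Mapping[str, int] = field(
        default_factory=lambda: dict(ORGANELLE_BLOCK_SIZES)
    )
    n_electrodes: int = 8
    n_vehicle_wells: int = 6
    outlier_fraction: float = 0.01
    noise_sigma: float = 0.25
    #: SD of the well-level global nuisance factor (confluence / staining
    #: intensity) that loads on all features with fixed positive weights and
    #: induces the feature-feature correlation structure of real imaging data.
    well_factor_sigma: float = 0.1
    line_baseline_sigma: float = 0.3
    line_ec50_shift: float = 0.5  # per-line EC50 shift, ± log10 units
    #: Mild nonspecific stress response shared by all compounds at high
    #: exposure (log-fold change per organelle block at maximal effect):
    #: secretory-pathway and lysosomal drift that dose-correlates even for
    #: compounds without a specific organelle mechanism.
    nonspecific_stress: Mapping[str, float] = field(
        default_factory=lambda: {"er": 0.08, "golgi": 0.06, "lysosomes": 0.04}
    )
    recording_s: float = 300.0
    base_bpm: float = 30.0
    base_fpd_ms: float = 400.0
    base_electrode_cv: float = 0.01
    beat_noise_cv: float = 0.02
    low_amplitude_fraction: float = 0.05
    fpd_detect_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValueError("design needs at least one compound")
        if not self.lines:
            raise ValueError("design needs at least one cell line")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥ 1")
        if sum(self.organelle_blocks.values()) != self.n_features:
            raise ValueError("organelle blocks must partition exactly n_features indices")
        names = {c.name for c in self.compounds}
        if len(names) != len(self.compounds):
            raise ValueError("compound names must be unique")

    @property
    def feature_names(self) -> list[str]:
        return build_feature_space(self.organelle_blocks)[0]

    @property
    def block_indices(self) -> dict[str, list[int]]:
        return build_feature_space(self.organelle_blocks)[1]

    def with_(self, **kwargs) -> "StudyDesign":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_compound_panel() -> tuple[CompoundSpec, ...]:
    """The 17-compound reference panel with its clinical concentration ranges.

    Groups are FDA-label cardiovascular risk categories; mechanism profiles
    encode each compound's dominant organelle phenotype (log-fold change at
    maximal effect). Four planted mechanism classes: 1 = genotoxic
    (doxorubicin alone), 2 = weak/no morphological effect, 3 = ion-channel
    blockers with mitochondrial/lysosomal phenotypes, 4 = mixed multi-organelle
    toxicity.
    """
    C = CompoundSpec
    E = EphysEffect
    return (
        C("doxorubicin", semilog_series(0.01, 10), "structural",
          {"dna_damage": 0.7, "nucleoli": 0.6, "nuclei": 0.5,
           "sarcomere": -0.25, "gap_junctions": 0.25, "golgi": 0.15,
           "lysosomes": 0.1},
          ec50=0.15, viability_effect=0.67, viability_ec50=1.0,
          ephys=E(bpm_shift=0.3, bri_inflation=0.12), mechanism_cluster=1),
        C("cisplatin", semilog_series(0.01, 10), "ischemia",
          {"gap_junctions": 0.3, "sarcomere": -0.3, "golgi": 0.22, "er": 0.18, "nuclei": -0.15},
          ec50=2.0, viability_effect=0.2, ephys=E(fpd_shift=0.15),
          mechanism_cluster=4),
        C("ponatinib", semilog_series(0.001, 1), "ischemia",
          {"gap_junctions": 0.3, "sarcomere": -0.3, "golgi": 0.22, "er": 0.18, "nuclei": -0.15},
          ec50=0.1, viability_effect=0.15,
          ephys=E(bpm_shift=-0.05, bri_inflation=0.03), mechanism_cluster=4),
        C("dasatinib", semilog_series(0.001, 1), "structural",
          {"gap_junctions": 0.3, "sarcomere": -0.3, "golgi": 0.22, "nuclei": 0.15, "er": -0.18},
          ec50=0.1, viability_effect=0.1, mechanism_cluster=4),
        C("lapatinib", semilog_series(0.01, 10), "structural",
          {"gap_junctions": 0.3, "sarcomere": -0.3, "golgi": 0.22,
           "nuclei": 0.15, "er": -0.18, "peroxisomes": -0.15},
          ec50=2.0, viability_effect=0.15,
          ephys=E(bri_inflation=0.03, quiescence_dose=10.0), mechanism_cluster=4),
        C("fluorouracil", semilog_series(0.01, 10), "ischemia",
          {"gap_junctions": 0.3, "sarcomere": -0.3, "golgi": 0.22, "er": 0.18, "nuclei": -0.15},
          ec50=2.0, viability_effect=0.1, mechanism_cluster=4),
        C("methotrexate", semilog_series(0.001, 1), "structural",
          {"gap_junctions": 0.3, "sarcomere": -0.3, "golgi": 0.22, "nuclei": 0.15, "er": -0.18},
          ec50=0.1, viability_effect=0.05, mechanism_cluster=4),
        C("omecamtiv", semilog_series(0.001, 1), "none",
          {}, ec50=0.1, mechanism_cluster=2),
        C("propofol", semilog_series(0.1, 100), "none",
          {}, ec50=20.0, mechanism_cluster=2),
        C("bupivacaine", semilog_series(0.01, 10), "arrhythmia",
          {"mitochondria": 0.4, "lysosomes": -0.3, "sarcomere": -0.1},
          ec50=2.0, ephys=E(bpm_shift=-0.3, bri_inflation=0.10),
          mechanism_cluster=3),
        C("amiodarone", semilog_series(0.01, 10), "arrhythmia",
          {"mitochondria": 0.6, "lysosomes": -0.35, "sarcomere": -0.1},
          ec50=0.4, viability_effect=0.31, viability_ec50=1.0,
          ephys=E(bpm_shift=-0.3, bri_inflation=0.08, quiescence_dose=3.0), mechanism_cluster=3),
        C("dofetilide", semilog_series(0.0001, 0.1), "arrhythmia",
          {"mitochondria": 0.4, "lysosomes": -0.25, "sarcomere": -0.1},
          ec50=0.005,
          ephys=E(bpm_shift=-0.15, bri_inflation=0.10, fpd_shift=0.15),
          mechanism_cluster=3),
        C("digoxin", semilog_series(0.00001, 0.01), "arrhythmia",
          {}, ec50=0.001,
          ephys=E(bpm_shift=-0.2, bri_inflation=0.10, fpd_shift=-0.1),
          mechanism_cluster=2),
        C("chlorpromazine", semilog_series(0.001, 1), "arrhythmia",
          {}, ec50=0.3, ephys=E(fpd_shift=0.04), mechanism_cluster=2),
        C("erlotinib", semilog_series(0.01, 10), "ischemia",
          {"gap_junctions": 0.3, "sarcomere": -0.3, "golgi": 0.22, "er": 0.18,
           "nuclei": -0.15},
          ec50=3.0, ephys=E(bri_inflation=0.03, fpd_shift=0.05),
          mechanism_cluster=4),
        C("aspirin", semilog_series(0.01, 10), "none", {}, ec50=3.0,
          mechanism_cluster=2),
        C("empagliflozin", semilog_series(0.001, 1), "none", {}, ec50=0.3,
          mechanism_cluster=2),
    )


def default_study_design(seed: int = 0, **overrides) -> StudyDesign:
    """The default screen: 17 compounds × 7 concentrations × 3 lines × 6 wells."""
    return StudyDesign(compounds=default_compound_panel(), seed=seed).with_(**overrides)
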