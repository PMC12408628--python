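import numpy as np
import pandas as pd
import pytest

from cardioprofiler.design import (
    CompoundSpec,
    EphysEffect,
    StudyDesign,
    default_compound_panel,
    semilog_series,
)
from cardioprofiler.simulate import generate_cell_features, generate_mea_recordings


def tiny_panel():
    """One compound per planted mechanism class, small concentration series."""
    C, E = CompoundSpec, EphysEffect
    return (
        C("genotoxin", semilog_series(0.01, 10),
          "structural", {"dna_damage": 0.7, "nucleoli": 0.6, "nuclei": 0.5},
          ec50=0.3, viability_effect=0.67, viability_ec50=1.0,
          ephys=E(bpm_shift=0.3, bri_inflation=0.12), mechanism_cluster=1),
        C("channelblock", semilog_series(0.001, 1),
          "arrhythmia", {"mitochondria": 0.6, "lysosomes": -0.35},
          ec50=0.05,
          ephys=E(bpm_shift=-0.3, bri_inflation=0.10, quiescence_dose=1.0),
          mechanism_cluster=3),
        C("mixedtox", semilog_series(0.01, 10),
          "ischemia", {"gap_junctions": 0.4, "sarcomere": -0.4, "er": 0.3},
          ec50=1.0, ephys=E(fpd_shift=0.2), mechanism_cluster=4),
        C("inert", semilog_series(0.001, 1), "none", {}, ec50=0.3,
          mechanism_cluster=2),
    )


@pytest.fixture(scope="session")
def tiny_design():
    return StudyDesign(
        compounds=tiny_panel(),
        lines=("lineA", "lineB"),
        n_replicates=3,
        cells_per_well=40,
        n_vehicle_wells=3,
        recording_s=60.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cells(tiny_design):
    return generate_cell_features(tiny_design)


@pytest.fixture(scope="session")
def tiny_mea(tiny_design):
    return generate_mea_recordings(tiny_design)


@pytest.fixture(scope="session")
def default_panel():
    return default_compound_panel()


def make_well_df(
    electrode_specs,
    well="P1_W001",
    plate="P1",
):
    """Build a long-format well event table from per-electrode specs.

    electrode_specs: list of dicts with keys periods (list of s), fpds
    (list of ms or None), amplitude (µV).
    """
    rows = []
    for e, spec in enumerate(electrode_specs, start=1):
        periods = spec.get("periods", [])
        fpds = spec.get("fpds")
        amp = spec.get("amplitude", 800.0)
        if not periods:
            rows.append((plate, well, e, -1, np.nan, np.nan, amp))
            continue
        for b, p in enumerate(periods):
            f = np.nan if fpds is None else fpds[b]
            rows.append((plate, well, e, b, p, f, amp))
    return pd.DataFrame(
        rows,
        columns=["plate", "well", "electrode", "beat_index", "beat_period_s",
                 "fpd_ms", "amplitude_uV"],
    )
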