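"""Study configuration and default parameterisation.

The default configuration encodes the study design this package emulates:
eight dairy cows sampled in milk and blood over a full lactation
(on average ~300 days, 291-305), twice a week for the first 100 days in
milk (DIM) and weekly thereafter, yielding ~55 samples per animal and
matrix.  Cell populations are parameterised as hierarchical fractions
(main populations of CD45+ leukocytes, subsets within each main
population) with per-animal offsets, lactation-stage trends, and
inflammation-episode shifts.  Marker intensities live on an
asinh-transformed scale; scatter channels are linear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

CHANNELS: tuple[str, ...] = (
    "FSC-A", "FSC-H", "SSC-A",
    "CD45", "CD14", "CD16", "CD11b", "CD335", "gdTCR",
    "CD4", "CD8", "CD21", "panCK", "Viability", "AF",
)

#: channels left untouched by the asinh transform
SCATTER_CHANNELS: frozenset[str] = frozenset({"FSC-A", "FSC-H", "SSC-A"})

#: terminal live-cell population labels, per matrix
BLOOD_POPULATIONS: tuple[str, ...] = (
    "neutrophils", "eosinophils", "immature_granulocytes",
    "cM", "intM", "ncM",
    "nk_cells", "gd_t_cells", "cd4_t_cells", "cd8_t_cells", "b_cells",
    "dn_lymphocytes",
    "cd45neg_other",
)
MILK_POPULATIONS: tuple[str, ...] = (
    "neutrophils", "eosinophils", "immature_granulocytes",
    "cMac", "ncMac",
    "nk_cells", "gd_t_cells", "cd4_t_cells", "cd8_t_cells", "b_cells",
    "dn_lymphocytes",
    "mec", "cd45neg_other",
)

#: nuisance event classes that gating must remove
NUISANCE_CLASSES: tuple[str, ...] = ("debris", "doublet", "dead")

# transformed-scale marker levels
_NEG = (0.4, 0.30)
_POS = (3.0, 0.30)
_DIM_LOW = (1.2, 0.30)   # CD11b on immature granulocytes
_AF_HI = (2.6, 0.35)     # eosinophil autofluorescence
_AF_LO = (0.6, 0.35)
_VIA_DEAD = (3.2, 0.30)

# linear scatter levels per lineage: (FSC-A loc, scale), (SSC-A loc, scale)
_SCATTER = {
    "lymphocyte": ((55_000, 7_000), (18_000, 3_500)),
    "monocyte": ((75_000, 8_000), (50_000, 5_000)),
    "granulocyte": ((70_000, 8_000), (95_000, 7_000)),
    "mec": ((90_000, 10_000), (40_000, 8_000)),
    "cd45neg_other": ((40_000, 9_000), (25_000, 8_000)),
    "debris": ((4_000, 2_000), (2_500, 1_200)),
    "dead": ((65_000, 12_000), (55_000, 20_000)),
}

_LINEAGE = {
    "neutrophils": "granulocyte", "eosinophils": "granulocyte",
    "immature_granulocytes": "granulocyte",
    "cM": "monocyte", "intM": "monocyte", "ncM": "monocyte",
    "cMac": "monocyte", "ncMac": "monocyte",
    "nk_cells": "lymphocyte", "gd_t_cells": "lymphocyte",
    "cd4_t_cells": "lymphocyte", "cd8_t_cells": "lymphocyte",
    "b_cells": "lymphocyte", "dn_lymphocytes": "lymphocyte",
    "mec": "mec", "cd45neg_other": "cd45neg_other",
}

# marker positivity per population; anything unlisted is negative.
# a value may be a single (loc, scale) or a tuple of (weight, loc, scale)
# mixture components (used for the CD14+/- nonclassical macrophages).
_MARKER_POS: dict[str, dict[str, Any]] = {
    "neutrophils": {"CD11b": _POS},
    "eosinophils": {"CD11b": _POS, "AF": _AF_HI},
    "immature_granulocytes": {"CD11b": _DIM_LOW},
    "cM": {"CD14": _POS, "CD11b": _POS},
    "intM": {"CD14": _POS, "CD16": _POS, "CD11b": _POS},
    "ncM": {"CD16": _POS, "CD11b": _POS},
    "cMac": {"CD14": _POS, "CD11b": _POS},
    "ncMac": {"CD16": _POS, "CD11b": _POS,
              "CD14": ((0.5, 3.0, 0.30), (0.5, 0.4, 0.30))},
    "nk_cells": {"CD335": _POS},
    "gd_t_cells": {"gdTCR": _POS},
    "cd4_t_cells": {"CD4": _POS},
    "cd8_t_cells": {"CD8": _POS},
    "b_cells": {"CD21": _POS},
    "dn_lymphocytes": {},
    "mec": {"panCK": _POS},
    "cd45neg_other": {},
}

_CD45_NEGATIVE = {"mec", "cd45neg_other", "debris"}


def _normalise(sig: Any) -> tuple[tuple[float, float, float], ...]:
    """Coerce a signature entry to a tuple of (weight, loc, scale)."""
    if isinstance(sig[0], (tuple, list)):
        return tuple(tuple(c) for c in sig)
    loc, scale = sig
    return ((1.0, float(loc), float(scale)),)


def build_signatures(separation: float = 1.0) -> dict[str, dict[str, tuple]]:
    """Per-population, per-channel mixture signatures on transformed scale.

    ``separation`` rescales the distance of every positive marker level
    from its negative counterpart; 0 collapses all populations onto the
    negative level (used to verify that marker separation is what makes
    populations recoverable).
    """
    sigs: dict[str, dict[str, tuple]] = {}
    all_pops = set(_LINEAGE) | set(NUISANCE_CLASSES)
    for pop in all_pops:
        lineage = _LINEAGE.get(pop, pop)
        (fsc, ssc) = _SCATTER.get(lineage, _SCATTER["dead"])[0], \
            _SCATTER.get(lineage, _SCATTER["dead"])[1]
        chan: dict[str, tuple] = {"FSC-A": _normalise(fsc), "SSC-A": _normalise(ssc)}
        for marker in ("CD45", "CD14", "CD16", "CD11b", "CD335", "gdTCR",
                       "CD4", "CD8", "CD21", "panCK", "Viability"):
            chan[marker] = _normalise(_NEG)
        chan["AF"] = _normalise(_AF_LO)
        if pop not in _CD45_NEGATIVE and pop != "doublet":
            chan["CD45"] = _normalise(_POS)
        if pop == "dead":
            chan["CD45"] = _normalise(_POS)
            chan["Viability"] = _normalise(_VIA_DEAD)
        if pop == "doublet":
            # aggregates look like large CD45+ cells; FSC-A doubled at draw
            chan["CD45"] = _normalise(_POS)
            chan["FSC-A"] = _normalise(_SCATTER["lymphocyte"][0])
            chan["SSC-A"] = _normalise((30_000, 10_000))
        for marker, level in _MARKER_POS.get(pop, {}).items():
            chan[marker] = _normalise(level)
        if separation != 1.0:
            scaled: dict[str, tuple] = {}
            for ch, comps in chan.items():
                if ch in SCATTER_CHANNELS or ch == "Viability":
                    scaled[ch] = comps
                else:
                    neg_loc = _NEG[0] if ch != "AF" else _AF_LO[0]
                    scaled[ch] = tuple(
                        (w, neg_loc + (loc - neg_loc) * separation, sc)
                        for (w, loc, sc) in comps)
            chan = scaled
        sigs[pop] = chan
    return sigs


@dataclass
class EpisodeParams:
    """Inflammation-episode generator settings.

    Episodes mimic (sub)clinical inflammation detectable through the acute
    phase protein haptoglobin; during an episode milk gamma-delta T cells
    shift down and milk CD4+ T cells up, while immature granulocytes are
    deliberately left untouched.
    """
    rate_per_lactation: float = 1.0
    duration_days: tuple[int, int] = (10, 22)
    haptoglobin_amplitude: float = 0.40   # g/L above baseline
    gdt_shift: float = -0.08              # fraction-of-lymphocytes delta
    cd4_shift: float = 0.06
    immature_gran_shift: float = 0.0      # kept 0: known null result


@dataclass
class BiomarkerParams:
    baseline: float
    early_amplitude: float
    decay_tau: float       # days
    noise_cv: float = 0.10


def default_biomarkers() -> dict[str, BiomarkerParams]:
    """Serum panel: negative-energy-balance markers spike after calving
    and decay exponentially; calcium dips briefly; haptoglobin is driven
    by the episode machinery (plus a calving window) and parameterised in
    :class:`StudyConfig` directly."""
    return {
        "NEFA": BiomarkerParams(0.25, 0.60, 25.0),        # mmol/L
        "BHBA": BiomarkerParams(0.60, 0.50, 30.0),        # mmol/L
        "bilirubin": BiomarkerParams(2.0, 4.0, 15.0),     # umol/L
        "GLDH": BiomarkerParams(12.0, 10.0, 40.0),        # U/L
        "calcium": BiomarkerParams(2.4, -0.25, 8.0, 0.03),  # mmol/L
    }


@dataclass
class TrajectoryParams:
    """Population mean-trend and noise parameters, shared across animals.

    Milk granulocyte/lymphocyte fractions fluctuate strongly early in
    lactation and level out around ``level_out_dim``; milk gamma-delta
    T cells decline while CD4+ T cells rise; blood fractions are
    stationary around per-animal baselines.
    """
    # --- milk, main populations (fractions of CD45+) ---
    milk_gran_early: float = 0.45
    milk_gran_late: float = 0.62
    milk_gran_center: float = 120.0
    milk_gran_width: float = 30.0
    milk_mono: float = 0.10
    milk_main_sd_early: float = 0.10
    milk_main_sd_late: float = 0.04
    level_out_dim: float = 150.0
    level_out_width: float = 25.0
    # --- milk lymphocyte subsets (fractions of lymphocytes) ---
    milk_gdt_intercept: float = 0.42
    milk_gdt_slope: float = -0.0011      # per DIM: decline continues all lactation
    milk_gdt_step: float = -0.02
    milk_gdt_step_center: float = 100.0
    milk_gdt_step_width: float = 40.0
    milk_cd4_intercept: float = 0.07
    milk_cd4_slope: float = 0.0009
    milk_cd4_step: float = 0.03
    # end-of-lactation involution shift (steeper T-cell change toward dry-off)
    milk_cd4_involution: float = 0.04
    milk_gdt_involution: float = -0.03
    involution_center: float = 260.0
    involution_width: float = 25.0
    milk_lymph_subset_sd_early: float = 0.035
    milk_lymph_subset_sd_late: float = 0.015
    milk_nk: float = 0.04
    milk_cd8: float = 0.26
    milk_b: float = 0.05
    milk_small_subset_sd: float = 0.012
    # --- milk granulocyte / macrophage subsets ---
    milk_eos: float = 0.03
    milk_immature: float = 0.05
    milk_cmac: float = 0.60
    milk_mac_sd: float = 0.05
    # --- milk viability and CD45- classes ---
    milk_viability_plateau: float = 0.93
    milk_viability_drop: float = 0.43
    milk_viability_tau: float = 40.0
    milk_viability_sd: float = 0.03
    milk_mec_fraction: float = 0.03      # of live cells
    milk_cd45neg_other: float = 0.02
    # --- blood (stationary) ---
    blood_gran: float = 0.50
    blood_gran_sd: float = 0.04
    blood_mono: float = 0.12
    blood_mono_sd: float = 0.015
    blood_eos: float = 0.08
    blood_immature: float = 0.05
    blood_gran_subset_sd: float = 0.012
    blood_cm: float = 0.70
    blood_intm: float = 0.15
    blood_mono_subset_sd: float = 0.03
    blood_nk: float = 0.08
    blood_gdt: float = 0.18
    blood_cd4_mean: float = 0.27         # population mean; per-animal offsets apply
    blood_cd4_between_sd: float = 0.05
    blood_cd4_visit_sd: float = 0.025
    blood_cd8: float = 0.12
    blood_b: float = 0.17
    blood_lymph_subset_sd: float = 0.018
    blood_viability: float = 0.97
    blood_viability_sd: float = 0.008
    blood_cd45neg_other: float = 0.015


@dataclass
class StudyConfig:
    n_animals: int = 8
    lactation_days_range: tuple[int, int] = (291, 305)
    twice_weekly_until: int = 100
    dropout_prob: float = 0.035
    events_per_sample: int = 50_000
    debris_fraction: float = 0.06
    doublet_fraction: float = 0.04
    panel: tuple[str, ...] = CHANNELS
    cofactor: float = 150.0
    animal_effect_sd: float = 0.03
    signature_separation: float = 1.0
    mec_available_from_dim: int = 50
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    episodes: EpisodeParams = field(default_factory=EpisodeParams)
    biomarkers: dict[str, BiomarkerParams] = field(default_factory=default_biomarkers)
    haptoglobin_baseline: float = 0.08    # g/L
    haptoglobin_sd: float = 0.015
    haptoglobin_calving_amplitude: float = 0.04
    haptoglobin_calving_tau: float = 5.0
    seed: int = 0

    #: named per-animal blood CD4+ (of lymphocytes) baselines; animals
    #: without an entry draw their baseline from the between-animal spread
    named_cd4_profiles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"cow1": (0.347, 0.029), "cow6": (0.197, 0.026)})

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.animal_effect_sd < 0:
            raise ValueError("animal_effect_sd must be non-negative")
        for name, bp in self.biomarkers.items():
            if bp.baseline < 0:
                raise ValueError(f"negative baseline for biomarker {name!r}")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")

    @property
    def haptoglobin_threshold(self) -> float:
        """Episode-calling cutoff: baseline + 3 x baseline SD."""
        return self.haptoglobin_baseline + 3.0 * self.haptoglobin_sd

    def signatures(self) -> dict[str, dict[str, tuple]]:
        return build_signatures(self.signature_separation)

    # --- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "StudyConfig":
        doc = dict(doc)
        if "trajectory" in doc and isinstance(doc["trajectory"], dict):
            doc["trajectory"] = TrajectoryParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in doc["trajectory"].items()})
        if "episodes" in doc and isinstance(doc["episodes"], dict):
            ep = dict(doc["episodes"])
            if isinstance(ep.get("duration_days"), list):
                ep["duration_days"] = tuple(ep["duration_days"])
            doc["episodes"] = EpisodeParams(**ep)
        if "biomarkers" in doc:
            doc["biomarkers"] = {
                k: BiomarkerParams(**v) if isinstance(v, dict) else v
                for k, v in doc["biomarkers"].items()}
        for key in ("lactation_days_range", "panel"):
            if isinstance(doc.get(key), list):
                doc[key] = tuple(doc[key])
        if "named_cd4_profiles" in doc:
            doc["named_cd4_profiles"] = {
                k: tuple(v) for k, v in doc["named_cd4_profiles"].items()}
        return cls(**doc)
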