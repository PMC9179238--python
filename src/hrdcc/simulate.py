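"""Synthetic longitudinal study generator.

Generates the full study this package analyses: per-animal sampling
schedules, latent cell-population trajectories in milk and blood,
inflammation episodes, serum biomarkers, and event-level cytometry
samples with hidden truth labels.

The hierarchy of latent quantities mirrors the gating tree: main
populations (granulocytes, monocytes/macrophages, lymphocytes) as
fractions of CD45+ leukocytes, subsets as fractions of their parent, a
viability fraction, and CD45- classes (mammary epithelial cells and a
small residual class) as fractions of live cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    BLOOD_POPULATIONS,
    MILK_POPULATIONS,
    SCATTER_CHANNELS,
    StudyConfig,
    TrajectoryParams,
)
from .events import EventMatrix


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# schedules and profiles
# ---------------------------------------------------------------------------

def generate_schedule(lactation_days: int, twice_weekly_until: int,
                      dropout_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Sampling days (DIM) for one animal and matrix.

    Day 1 is always scheduled; visits then fall twice a week until the
    cutoff and weekly afterwards.  Each scheduled visit is independently
    missed with probability ``dropout_prob``.
    """
    if lactation_days < twice_weekly_until + 1:
        raise ValueError(
            f"lactation of {lactation_days} d is shorter than the twice-weekly "
            f"cutoff of {twice_weekly_until} d")
    days = [1]
    week = 0
    while True:
        for offset in (4, 7):
            day = week * 7 + offset
            if day <= twice_weekly_until:
                days.append(day)
        if week * 7 + 7 > twice_weekly_until:
            break
        week += 1
    day = days[-1] + 7
    while day <= lactation_days:
        days.append(day)
        day += 7
    days = np.array(sorted(set(days)), dtype=int)
    if dropout_prob > 0:
        keep = rng.random(len(days)) >= dropout_prob
        days = days[keep]
    return days


@dataclass
class AnimalProfile:
    """Per-animal baselines: lactation length and additive offsets on the
    population fractions, plus an explicit blood CD4+ (of lymphocytes)
    mean and per-visit SD since those carry the named-cow defaults."""
    animal_id: str
    lactation_days: int
    blood_cd4_mean: float
    blood_cd4_visit_sd: float
    offsets: dict[str, float] = field(default_factory=dict)

    def offset(self, key: str) -> float:
        return self.offsets.get(key, 0.0)


# per-offset SD as a multiple of animal_effect_sd; small populations and
# the phase-trending milk T-cell subsets get proportionally tighter spreads
# (between-cow variation is widest in the stationary blood baselines)
_OFFSET_SD_FACTOR = {
    "milk_gran": 1.0, "milk_mono": 0.4, "milk_gdt": 0.5, "milk_cd4": 0.5,
    "milk_cd8": 1.0, "milk_b": 0.2, "milk_nk": 0.16,
    "blood_gran": 1.0, "blood_mono": 0.48, "blood_nk": 0.32,
    "blood_gdt": 0.72, "blood_cd8": 0.48, "blood_b": 0.68,
}


def generate_animal_profiles(config: StudyConfig,
                             rng: np.random.Generator) -> list[AnimalProfile]:
    """Draw per-animal profiles.

    Animals named in ``config.named_cd4_profiles`` (by default cow1 and
    cow6) get fixed blood CD4+ baselines; the rest draw theirs from the
    between-animal spread.  Other offsets are zero-mean Gaussian with SD
    shrunk for small populations so fractions stay in (0, 1).
    """
    if config.n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    tp = config.trajectory
    lo, hi = config.lactation_days_range
    profiles = []
    for i in range(1, config.n_animals + 1):
        name = f"cow{i}"
        lactation = int(rng.integers(lo, hi + 1))
        if name in config.named_cd4_profiles:
            cd4_mean, cd4_sd = config.named_cd4_profiles[name]
        else:
            cd4_mean = float(np.clip(
                rng.normal(tp.blood_cd4_mean, tp.blood_cd4_between_sd), 0.08, 0.45))
            cd4_sd = tp.blood_cd4_visit_sd
        offsets = {}
        for key, factor in _OFFSET_SD_FACTOR.items():
            sd = config.animal_effect_sd * factor
            offsets[key] = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        profiles.append(AnimalProfile(name, lactation, cd4_mean, cd4_sd, offsets))
    return profiles


# ---------------------------------------------------------------------------
# latent population states
# ---------------------------------------------------------------------------

@dataclass
class TruePopulationState:
    """Latent composition of one sample, on the gating hierarchy."""
    animal_id: str
    dim: int
    matrix: str                       # "milk" | "blood"
    main: dict[str, float]            # of CD45+, sums to 1
    gran_subsets: dict[str, float]    # of granulocytes, sums to 1
    mono_subsets: dict[str, float]    # of monocytes/macrophages, sums to 1
    lymph_subsets: dict[str, float]   # of lymphocytes, sums to 1
    cd45neg: dict[str, float]         # of live cells
    viability: float

    def __post_init__(self) -> None:
        for group in (self.main, self.gran_subsets, self.mono_subsets,
                      self.lymph_subsets):
            total = sum(group.values())
            if abs(total - 1.0) > 1e-9:
                for k in group:
                    group[k] /= total
        if not 0.0 <= self.viability <= 1.0:
            raise ValueError("viability must lie in [0, 1]")

    def terminal_fractions(self) -> dict[str, float]:
        """Terminal live-cell fractions; sums to 1."""
        leuk = 1.0 - sum(self.cd45neg.values())
        out: dict[str, float] = {}
        sub_of = {"granulocytes": self.gran_subsets,
                  "monocytes_macrophages": self.mono_subsets,
                  "lymphocytes": self.lymph_subsets}
        for parent, frac in self.main.items():
            for pop, sub in sub_of[parent].items():
                out[pop] = leuk * frac * sub
        out.update(self.cd45neg)
        return out

    def truth_percentages(self) -> dict[str, float]:
        """Percent-of-parent truth values matching the gating read-out."""
        out = {k: 100.0 * v for k, v in self.main.items()}
        for group in (self.gran_subsets, self.mono_subsets, self.lymph_subsets):
            out.update({k: 100.0 * v for k, v in group.items()})
        out["viability"] = 100.0 * self.viability
        if "mec" in self.cd45neg:
            denom = sum(self.cd45neg.values())
            out["mec"] = 100.0 * self.cd45neg["mec"] / denom if denom > 0 else 0.0
        return out


def _clip_frac(x: float, lo: float = 0.002, hi: float = 0.95) -> float:
    return float(np.clip(x, lo, hi))


def _draw_subsets(means: dict[str, float], sds: dict[str, float],
                  remainder: str, rng: np.random.Generator,
                  volatility: float) -> dict[str, float]:
    """Draw named subset fractions and assign the remainder; rescale if
    the draws exceed 0.98 so the remainder stays positive."""
    draws = {k: _clip_frac(rng.normal(m, volatility * sds[k]))
             for k, m in means.items()}
    total = sum(draws.values())
    if total > 0.98:
        draws = {k: v * 0.98 / total for k, v in draws.items()}
        total = 0.98
    draws[remainder] = 1.0 - total
    return draws


def _milk_means(tp: TrajectoryParams, profile: AnimalProfile, dim: float) -> dict:
    gran_raw = (tp.milk_gran_early
                + (tp.milk_gran_late - tp.milk_gran_early)
                * _sigmoid((dim - tp.milk_gran_center) / tp.milk_gran_width))
    mono_raw = tp.milk_mono
    involution = _sigmoid((dim - tp.involution_center) / tp.involution_width)
    gdt_raw = (tp.milk_gdt_intercept + tp.milk_gdt_slope * dim
               + tp.milk_gdt_step
               * _sigmoid((dim - tp.milk_gdt_step_center) / tp.milk_gdt_step_width)
               + tp.milk_gdt_involution * involution)
    cd4_raw = (tp.milk_cd4_intercept + tp.milk_cd4_slope * dim
               + tp.milk_cd4_step
               * _sigmoid((dim - tp.milk_gdt_step_center) / tp.milk_gdt_step_width)
               + tp.milk_cd4_involution * involution)
    for name, raw in (("gran", gran_raw), ("mono", mono_raw),
                      ("gdt", gdt_raw), ("cd4", cd4_raw)):
        if not 0.0 < raw < 1.0:
            raise ValueError(
                f"mean {name} fraction {raw:.3f} outside (0,1) at DIM {dim}")
    # per-animal offsets may not push a mean out of the open interval
    gran = _clip_frac(gran_raw + profile.offset("milk_gran"), 0.005, 0.95)
    mono = _clip_frac(mono_raw + profile.offset("milk_mono"), 0.005, 0.95)
    gdt = _clip_frac(gdt_raw + profile.offset("milk_gdt"), 0.005, 0.95)
    cd4 = _clip_frac(cd4_raw + profile.offset("milk_cd4"), 0.005, 0.95)
    viability = (tp.milk_viability_plateau
                 - tp.milk_viability_drop * np.exp(-dim / tp.milk_viability_tau))
    level = _sigmoid(-(dim - tp.level_out_dim) / tp.level_out_width)
    main_sd = (tp.milk_main_sd_late
               + (tp.milk_main_sd_early - tp.milk_main_sd_late) * level)
    subset_sd = (tp.milk_lymph_subset_sd_late
                 + (tp.milk_lymph_subset_sd_early - tp.milk_lymph_subset_sd_late)
                 * level)
    return {"gran": gran, "mono": mono, "gdt": gdt, "cd4": cd4,
            "viability": viability, "main_sd": float(main_sd),
            "subset_sd": float(subset_sd)}


def generate_trajectories(profile: AnimalProfile, schedule: np.ndarray,
                          matrix: str, tp: TrajectoryParams,
                          rng: np.random.Generator,
                          volatility: float = 1.0) -> list[TruePopulationState]:
    """Latent states at each scheduled visit.

    ``volatility`` scales every per-visit noise SD; 0 gives the
    deterministic mean curves.  Milk gamma-delta T cells decline and milk
    CD4+ T cells rise over lactation; milk granulocyte/lymphocyte noise
    is larger before the level-out DIM; blood is stationary around the
    animal's baseline.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be nonempty")
    if matrix not in ("milk", "blood"):
        raise ValueError(f"unknown matrix {matrix!r}")
    states = []
    for dim in schedule:
        dim = int(dim)
        if matrix == "milk":
            m = _milk_means(tp, profile, dim)
            gran = _clip_frac(rng.normal(m["gran"], volatility * m["main_sd"]), 0.05, 0.90)
            mono = _clip_frac(rng.normal(m["mono"], volatility * 0.03), 0.02, 0.40)
            if gran + mono > 0.95:
                scale = 0.95 / (gran + mono)
                gran, mono = gran * scale, mono * scale
            main = {"granulocytes": gran, "monocytes_macrophages": mono,
                    "lymphocytes": 1.0 - gran - mono}
            gran_sub = _draw_subsets(
                {"eosinophils": tp.milk_eos, "immature_granulocytes": tp.milk_immature},
                {"eosinophils": 0.008, "immature_granulocytes": tp.milk_small_subset_sd},
                "neutrophils", rng, volatility)
            mono_sub = _draw_subsets(
                {"cMac": tp.milk_cmac}, {"cMac": tp.milk_mac_sd},
                "ncMac", rng, volatility)
            lymph_sub = _draw_subsets(
                {"nk_cells": tp.milk_nk + profile.offset("milk_nk"),
                 "gd_t_cells": m["gdt"],
                 "cd4_t_cells": m["cd4"],
                 "cd8_t_cells": tp.milk_cd8 + profile.offset("milk_cd8"),
                 "b_cells": tp.milk_b + profile.offset("milk_b")},
                {"nk_cells": tp.milk_small_subset_sd,
                 "gd_t_cells": m["subset_sd"],
                 "cd4_t_cells": m["subset_sd"],
                 "cd8_t_cells": 0.03,
                 "b_cells": tp.milk_small_subset_sd},
                "dn_lymphocytes", rng, volatility)
            viability = _clip_frac(
                rng.normal(m["viability"], volatility * tp.milk_viability_sd), 0.05, 0.995)
            cd45neg = {"mec": tp.milk_mec_fraction,
                       "cd45neg_other": tp.milk_cd45neg_other}
        else:
            gran = _clip_frac(
                rng.normal(tp.blood_gran + profile.offset("blood_gran"),
                           volatility * tp.blood_gran_sd), 0.05, 0.90)
            mono = _clip_frac(
                rng.normal(tp.blood_mono + profile.offset("blood_mono"),
                           volatility * tp.blood_mono_sd), 0.02, 0.40)
            if gran + mono > 0.95:
                scale = 0.95 / (gran + mono)
                gran, mono = gran * scale, mono * scale
            main = {"granulocytes": gran, "monocytes_macrophages": mono,
                    "lymphocytes": 1.0 - gran - mono}
            gran_sub = _draw_subsets(
                {"eosinophils": tp.blood_eos, "immature_granulocytes": tp.blood_immature},
                {"eosinophils": 0.015, "immature_granulocytes": tp.blood_gran_subset_sd},
                "neutrophils", rng, volatility)
            mono_sub = _draw_subsets(
                {"cM": tp.blood_cm, "intM": tp.blood_intm},
                {"cM": tp.blood_mono_subset_sd, "intM": 0.02},
                "ncM", rng, volatility)
            lymph_sub = _draw_subsets(
                {"nk_cells": tp.blood_nk + profile.offset("blood_nk"),
                 "gd_t_cells": tp.blood_gdt + profile.offset("blood_gdt"),
                 "cd4_t_cells": profile.blood_cd4_mean,
                 "cd8_t_cells": tp.blood_cd8 + profile.offset("blood_cd8"),
                 "b_cells": tp.blood_b + profile.offset("blood_b")},
                {"nk_cells": 0.012,
                 "gd_t_cells": tp.blood_lymph_subset_sd,
                 "cd4_t_cells": profile.blood_cd4_visit_sd,
                 "cd8_t_cells": 0.012,
                 "b_cells": tp.blood_lymph_subset_sd},
                "dn_lymphocytes", rng, volatility)
            viability = _clip_frac(
                rng.normal(tp.blood_viability, volatility * tp.blood_viability_sd),
                0.5, 0.999)
            cd45neg = {"cd45neg_other": tp.blood_cd45neg_other}
        states.append(TruePopulationState(
            profile.animal_id, dim, matrix, main, gran_sub, mono_sub,
            lymph_sub, cd45neg, viability))
    return states


# ---------------------------------------------------------------------------
# inflammation episodes
# ---------------------------------------------------------------------------

@dataclass
class Episode:
    animal_id: str
    start: int
    end: int

    def contains(self, dim: int) -> bool:
        return self.start <= dim <= self.end


def draw_episode_windows(animal_id: str, lactation_days: int, rate: float,
                         duration_days: tuple[int, int],
                         rng: np.random.Generator,
                         forced: list[tuple[int, int]] | None = None) -> list[Episode]:
    """Draw inflammation windows for one animal (Poisson count per
    lactation, uniform onset, uniform duration); overlapping windows are
    merged.  ``forced`` windows are added deterministically."""
    windows: list[tuple[int, int]] = list(forced or [])
    n = rng.poisson(rate)
    for _ in range(n):
        dur = int(rng.integers(duration_days[0], duration_days[1] + 1))
        start = int(rng.integers(1, max(2, lactation_days - dur)))
        windows.append((start, start + dur))
    if not windows:
        return []
    windows.sort()
    merged = [list(windows[0])]
    for start, end in windows[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [Episode(animal_id, s, e) for s, e in merged]


def inject_episodes(states: list[TruePopulationState], episodes: list[Episode],
                    gdt_shift: float, cd4_shift: float,
                    immature_shift: float = 0.0) -> list[TruePopulationState]:
    """Apply in-episode composition shifts to milk states in place.

    Gamma-delta T cells shift by ``gdt_shift`` and CD4+ T cells by
    ``cd4_shift`` (fractions of lymphocytes); the double-negative
    remainder absorbs the net change.  Immature granulocytes are left
    untouched by default, encoding the known null association between
    inflammation and immature granulocytes.
    """
    dims = [s.dim for s in states]
    if dims != sorted(dims):
        raise ValueError("states must be sorted by DIM")
    for state in states:
        if state.matrix != "milk":
            continue
        if not any(ep.contains(state.dim) for ep in episodes):
            continue
        ls = state.lymph_subsets
        new_gdt = _clip_frac(ls["gd_t_cells"] + gdt_shift)
        new_cd4 = _clip_frac(ls["cd4_t_cells"] + cd4_shift)
        delta = (new_gdt - ls["gd_t_cells"]) + (new_cd4 - ls["cd4_t_cells"])
        ls["gd_t_cells"], ls["cd4_t_cells"] = new_gdt, new_cd4
        ls["dn_lymphocytes"] = _clip_frac(ls["dn_lymphocytes"] - delta, 0.0, 1.0)
        total = sum(ls.values())
        for k in ls:
            ls[k] /= total
        if immature_shift != 0.0:
            gs = state.gran_subsets
            gs["immature_granulocytes"] = _clip_frac(
                gs["immature_granulocytes"] + immature_shift)
            total = sum(gs.values())
            for k in gs:
                gs[k] /= total
    return states


# ---------------------------------------------------------------------------
# serum biomarkers
# ---------------------------------------------------------------------------

def generate_biomarkers(profile: AnimalProfile, schedule: np.ndarray,
                        episodes: list[Episode], config: StudyConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Serum analyte series at the given visits.

    Negative-energy-balance markers (NEFA, beta-HBA, bilirubin, GLDH)
    start elevated and decay exponentially to baseline; calcium dips
    briefly after calving; haptoglobin sits at baseline except during
    inflammation episodes and a small calving window.  All values are
    strictly positive.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be nonempty")
    rows = []
    dims = np.asarray(schedule, dtype=float)
    for analyte, bp in config.biomarkers.items():
        mean = bp.baseline + bp.early_amplitude * np.exp(-dims / bp.decay_tau)
        noise = rng.normal(1.0, bp.noise_cv, size=len(dims))
        values = np.maximum(mean * noise, 1e-3)
        for d, v in zip(schedule, values):
            rows.append((profile.animal_id, int(d), analyte, float(v)))
    hp_mean = (config.haptoglobin_baseline
               + config.haptoglobin_calving_amplitude
               * np.exp(-dims / config.haptoglobin_calving_tau))
    in_episode = np.array([any(ep.contains(int(d)) for ep in episodes)
                           for d in schedule])
    hp_mean = hp_mean + config.episodes.haptoglobin_amplitude * in_episode
    hp = np.maximum(hp_mean + rng.normal(0.0, config.haptoglobin_sd, len(dims)), 1e-3)
    for d, v in zip(schedule, hp):
        rows.append((profile.animal_id, int(d), "haptoglobin", float(v)))
    return pd.DataFrame(rows, columns=["animal_id", "dim", "analyte", "value"])


# ---------------------------------------------------------------------------
# event-level synthesis
# ---------------------------------------------------------------------------

def _draw_channel(comps: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n values from a 1-2 component Gaussian mixture signature."""
    if len(comps) == 1:
        _, loc, scale = comps[0]
        return rng.normal(loc, scale, n)
    weights = np.array([c[0] for c in comps])
    choice = rng.choice(len(comps), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for i, (_, loc, scale) in enumerate(comps):
        mask = choice == i
        out[mask] = rng.normal(loc, scale, int(mask.sum()))
    return out


def synthesize_events(state: TruePopulationState, config: StudyConfig,
                      rng: np.random.Generator,
                      n_events: int | None = None) -> EventMatrix:
    """Draw one sample's event matrix from the latent state.

    Events come from per-population location-scale clusters: markers on
    the asinh scale mapped back to the instrument scale via
    ``sinh(z) * cofactor``, scatter linear.  Doublets get FSC-A about
    twice FSC-H, dead events a high viability-dye signal, debris low
    scatter.  The milk panCK channel is omitted (not zeroed) before the
    configured DIM, so downstream code must cope with a missing channel.
    """
    n_events = int(n_events if n_events is not None else config.events_per_sample)
    if n_events < 1000:
        raise ValueError("n_events must be >= 1000")
    signatures = config.signatures()
    panel = [c for c in config.panel]
    if (state.matrix == "milk" and state.dim < config.mec_available_from_dim
            and "panCK" in panel):
        panel = [c for c in panel if c != "panCK"]

    terminal = state.terminal_fractions()
    expected_pops = MILK_POPULATIONS if state.matrix == "milk" else BLOOD_POPULATIONS
    for pop in terminal:
        if pop not in signatures:
            raise ValueError(f"no signature defined for population {pop!r}")
        for ch in panel:
            if ch != "FSC-H" and ch not in signatures[pop]:
                raise ValueError(f"population {pop!r} lacks channel {ch!r}")
    missing = set(terminal) - set(expected_pops)
    if missing:
        raise ValueError(f"unknown populations for matrix {state.matrix}: {missing}")

    p_debris = config.debris_fraction
    p_doublet = config.doublet_fraction
    p_cells = 1.0 - p_debris - p_doublet
    classes = ["debris", "doublet", "dead"] + list(terminal)
    probs = [p_debris, p_doublet, p_cells * (1.0 - state.viability)]
    probs += [p_cells * state.viability * f for f in terminal.values()]
    probs = np.asarray(probs)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_events, probs)

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    draw_cols = [c for c in panel if c != "FSC-H"]
    for cls, n in zip(classes, counts):
        if n == 0:
            continue
        sig = signatures[cls]
        block = np.empty((n, len(panel)))
        col_values: dict[str, np.ndarray] = {}
        for ch in draw_cols:
            z = _draw_channel(sig[ch], n, rng)
            if ch in SCATTER_CHANNELS:
                col_values[ch] = np.maximum(z, 1.0)
            else:
                col_values[ch] = np.sinh(z) * config.cofactor
        fsc_a = col_values["FSC-A"]
        if cls == "doublet":
            fsc_h = fsc_a.copy()
            fsc_a = 2.0 * fsc_h * rng.normal(1.0, 0.03, n)
            col_values["FSC-A"] = fsc_a
        else:
            fsc_h = fsc_a / rng.normal(1.0, 0.03, n)
        col_values["FSC-H"] = np.maximum(fsc_h, 1.0)
        for j, ch in enumerate(panel):
            block[:, j] = col_values[ch]
        blocks.append(block)
        labels.append(np.full(n, cls, dtype=object))

    data = np.concatenate(blocks, axis=0)
    all_labels = np.concatenate(labels)
    order = rng.permutation(len(data))
    frame = pd.DataFrame(data[order], columns=panel)
    sample_id = f"{state.animal_id}_{state.matrix}_d{state.dim:03d}"
    return EventMatrix(sample_id, frame, all_labels[order],
                       {"animal_id": state.animal_id, "dim": state.dim,
                        "matrix": state.matrix})


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudySet:
    """One simulated study: metadata, latent states, episodes, biomarkers.

    Event matrices are synthesised on demand from per-sample child seeds
    so the full study never has to sit in memory at once and any sample
    is reproducible in isolation.
    """
    config: StudyConfig
    seed: int
    profiles: list[AnimalProfile]
    samples: pd.DataFrame                    # sample_id, animal_id, dim, matrix
    states: dict[str, TruePopulationState]
    episodes: list[Episode]
    biomarkers: pd.DataFrame

    def events_for(self, sample_id: str,
                   n_events: int | None = None) -> EventMatrix:
        state = self.states[sample_id]
        row = self.samples.loc[self.samples.sample_id == sample_id].iloc[0]
        ss = np.random.SeedSequence(
            entropy=self.seed,
            spawn_key=(3, int(row.animal_index),
                       0 if row.matrix == "milk" else 1, int(row.visit_index)))
        return synthesize_events(state, self.config, np.random.default_rng(ss),
                                 n_events=n_events)

    def episodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.animal_id, e.start, e.end) for e in self.episodes],
            columns=["animal_id", "start", "end"])

    def truth_frame(self) -> pd.DataFrame:
        """Long table of latent percent-of-parent truth values."""
        rows = []
        for sid, st in self.states.items():
            for node, pct in st.truth_percentages().items():
                rows.append((sid, st.animal_id, st.dim, st.matrix, node, pct))
        return pd.DataFrame(rows, columns=[
            "sample_id", "animal_id", "dim", "matrix", "node", "percent"])


def simulate_study(config: StudyConfig | None = None, seed: int | None = None,
                   volatility: float = 1.0,
                   forced_episodes: dict[str, list[tuple[int, int]]] | None = None,
                   ) -> StudySet:
    """Generate a complete study (without event-level data, which
    :meth:`StudySet.events_for` synthesises lazily).

    ``forced_episodes`` maps animal_id to fixed (start, end) windows, for
    controlled experiments on episode detection.
    """
    config = config or StudyConfig()
    seed = config.seed if seed is None else int(seed)

    profile_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    profiles = generate_animal_profiles(config, profile_rng)

    sample_rows = []
    states: dict[str, TruePopulationState] = {}
    episodes: list[Episode] = []
    biomarker_frames = []
    ep = config.episodes
    for ai, profile in enumerate(profiles):
        ep_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1, ai)))
        animal_eps = draw_episode_windows(
            profile.animal_id, profile.lactation_days, ep.rate_per_lactation,
            ep.duration_days, ep_rng,
            forced=(forced_episodes or {}).get(profile.animal_id))
        episodes.extend(animal_eps)
        for mi, matrix in enumerate(("milk", "blood")):
            sched_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(2, ai, mi, 0)))
            schedule = generate_schedule(
                profile.lactation_days, config.twice_weekly_until,
                config.dropout_prob, sched_rng)
            traj_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(2, ai, mi, 1)))
            traj = generate_trajectories(
                profile, schedule, matrix, config.trajectory, traj_rng,
                volatility=volatility)
            if matrix == "milk":
                inject_episodes(traj, animal_eps, ep.gdt_shift, ep.cd4_shift,
                                ep.immature_gran_shift)
            for vi, state in enumerate(traj):
                sid = f"{profile.animal_id}_{matrix}_d{state.dim:03d}"
                states[sid] = state
                sample_rows.append((sid, profile.animal_id, state.dim, matrix, ai, vi))
            if matrix == "blood":
                bio_rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(2, ai, mi, 2)))
                biomarker_frames.append(generate_biomarkers(
                    profile, schedule, animal_eps, config, bio_rng))

    samples = pd.DataFrame(sample_rows, columns=[
        "sample_id", "animal_id", "dim", "matrix", "animal_index", "visit_index"])
    biomarkers = pd.concat(biomarker_frames, ignore_index=True)
    return StudySet(config, seed, profiles, samples, states, episodes, biomarkers)


def tiny_config(**overrides) -> StudyConfig:
    """A small-but-faithful configuration for fast exploratory runs:
    2 animals, 5,000 events per sample, full-length lactations."""
    defaults = dict(n_animals=2, events_per_sample=5_000)
    defaults.update(overrides)
    return StudyConfig(**defaults)
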