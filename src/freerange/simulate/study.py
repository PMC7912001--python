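"""Synthetic behavioural-test tables with planted effects.

Emulates the structure of a hen cohort crossed as rearing treatment
(control / novelty / structural) x ranging class (indoor / outdoor),
with hens housed in pens nested within rearing treatment:

* censored test latencies, log10-normal per cell with a pen random
  effect (tonic immobility, open-field and emergence latencies are all
  capped at 300 s);
* per-minute open-field counts (vocalisations, steps) from a Poisson
  model whose rate grows over the five test minutes for outdoor hens —
  the ranging x time interaction the study design anticipates;
* six-part feather scores (1-4 each, total 6-24) whose total is
  negatively coupled to the open-field step latency.

All generator parameters are retained in the returned ``truth`` dict so
downstream estimates can be compared with what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REARING = ("control", "novelty", "structural")
RANGING = ("indoor", "outdoor")


@dataclass(frozen=True)
class StudyEffectSpec:
    """Ground-truth parameters of one synthetic cohort."""

    n_per_cell: int = 22          # hens per rearing x ranging cell
    pens_per_rearing: int = 3     # 9 pens total, nested in rearing
    tests: tuple = ("OFT_step",)
    #: mean log10 latency (s) of outdoor hens
    baseline_log10_latency: float = 1.9
    #: indoor minus outdoor shift in mean log10 latency (fear effect)
    ranging_effect_log10: float = 0.0
    #: per-rearing shifts in mean log10 latency, same order as REARING
    rearing_effects_log10: tuple = (0.0, 0.0, 0.0)
    latency_log10_sd: float = 0.45
    pen_sd_log10: float = 0.08
    censor_s: float = 300.0
    #: per-minute count model: rate = base * exp(slope * (minute - 1))
    voc_rate_base: float = 2.0
    step_rate_base: float = 5.0
    rate_slope_outdoor: float = 0.25
    rate_slope_indoor: float = 0.0
    count_frailty_sd: float = 0.3   # hen-level log-normal frailty
    #: feather coupling: sqrt(total) = a + b * centred log10 step latency
    feather_sqrt_mean: float = 4.4  # ~ total 19
    feather_latency_slope: float = 0.0
    feather_sqrt_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for sd in (self.latency_log10_sd, self.pen_sd_log10,
                   self.count_frailty_sd, self.feather_sqrt_sd):
            if sd < 0:
                raise ValueError("all SDs must be >= 0")
        for rate in (self.voc_rate_base, self.step_rate_base):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class StudyTables:
    hens: pd.DataFrame           # hen_id, pen, rearing, ranging
    latencies: pd.DataFrame      # hen_id, pen, rearing, ranging, test, latency_s, censored
    minute_counts: pd.DataFrame  # hen_id, pen, rearing, ranging, minute, n_vocalisations, n_steps
    feather: pd.DataFrame        # hen_id, six part scores, total
    truth: dict


FEATHER_PARTS = ("neck", "chest", "back", "wing", "vent", "tail")


def generate_study_tables(spec: StudyEffectSpec) -> StudyTables:
    """Draw one cohort under the planted-effect specification."""
    rng = np.random.default_rng(spec.seed)

    # --- cohort layout: pens nested in rearing, both ranging classes per pen
    hen_rows = []
    hen = 0
    for ri, rearing in enumerate(REARING):
        pens = [f"pen{ri * spec.pens_per_rearing + p + 1}"
                for p in range(spec.pens_per_rearing)]
        for ranging in RANGING:
            for k in range(spec.n_per_cell):
                hen_rows.append(
                    {
                        "hen_id": f"hen{hen:03d}",
                        "pen": pens[k % len(pens)],
                        "rearing": rearing,
                        "ranging": ranging,
                    }
                )
                hen += 1
    hens = pd.DataFrame(hen_rows)
    pen_re = {p: rng.normal(0.0, spec.pen_sd_log10) for p in hens["pen"].unique()}
    rearing_shift = dict(zip(REARING, spec.rearing_effects_log10))

    # --- latencies, censored at the 300-s test maximum
    lat_rows = []
    step_log10 = {}
    for _, h in hens.iterrows():
        for test in spec.tests:
            mu = (
                spec.baseline_log10_latency
                + rearing_shift[h["rearing"]]
                + (spec.ranging_effect_log10 if h["ranging"] == "indoor" else 0.0)
                + pen_re[h["pen"]]
            )
            log_lat = rng.normal(mu, spec.latency_log10_sd)
            raw = 10.0 ** log_lat
            censored = raw >= spec.censor_s
            lat_rows.append(
                {
                    "hen_id": h["hen_id"],
                    "pen": h["pen"],
                    "rearing": h["rearing"],
                    "ranging": h["ranging"],
                    "test": test,
                    "latency_s": min(raw, spec.censor_s),
                    "censored": censored,
                }
            )
            if test == "OFT_step":
                step_log10[h["hen_id"]] = log_lat
    latencies = pd.DataFrame(lat_rows)

    # --- per-minute counts with ranging x time interaction
    cnt_rows = []
    for _, h in hens.iterrows():
        slope = (
            spec.rate_slope_outdoor if h["ranging"] == "outdoor"
            else spec.rate_slope_indoor
        )
        frailty = np.exp(rng.normal(0.0, spec.count_frailty_sd))
        for minute in range(1, 6):
            lam_v = spec.voc_rate_base * frailty * np.exp(slope * (minute - 1))
            lam_s = spec.step_rate_base * frailty * np.exp(slope * (minute - 1))
            cnt_rows.append(
                {
                    "hen_id": h["hen_id"],
                    "pen": h["pen"],
                    "rearing": h["rearing"],
                    "ranging": h["ranging"],
                    "minute": minute,
                    "n_vocalisations": rng.poisson(lam_v),
                    "n_steps": rng.poisson(lam_s),
                }
            )
    minute_counts = pd.DataFrame(cnt_rows)

    # --- feather scores coupled (optionally) to OFT step latency
    centred = None
    if step_log10:
        vals = np.array([step_log10[h] for h in hens["hen_id"]])
        centred = vals - vals.mean()
    fe_rows = []
    for i, h in hens.iterrows():
        latent = spec.feather_sqrt_mean + spec.feather_sqrt_sd * rng.standard_normal()
        if centred is not None:
            latent += spec.feather_latency_slope * centred[i]
        total = int(np.clip(round(latent ** 2), 6, 24))
        parts = _split_total(total, rng)
        fe_rows.append({"hen_id": h["hen_id"], **parts, "total": total})
    feather = pd.DataFrame(fe_rows)

    truth = {
        "spec": spec,
        "pen_effects": pen_re,
        "step_log10": step_log10,
    }
    return StudyTables(hens, latencies, minute_counts, feather, truth)


def _split_total(total: int, rng: np.random.Generator) -> dict:
    """Distribute a 6..24 total over six parts scored 1..4 each."""
    scores = np.ones(len(FEATHER_PARTS), dtype=int)
    surplus = total - len(scores)
    while surplus > 0:
        open_idx = np.flatnonzero(scores < 4)
        scores[rng.choice(open_idx)] += 1
        surplus -= 1
    return dict(zip(FEATHER_PARTS, scores.tolist()))
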