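"""Run configuration: YAML loading and seed/provenance metadata."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .clock import DAY, MINUTE
from .payments import PaymentAmounts
from .quality import FraudThresholds, PaymentTimingPolicy
from .sim import FraudConfig, SimConfig
from .population import PopulationModel


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    simulation: SimConfig = field(default_factory=SimConfig)
    population: PopulationModel = field(default_factory=PopulationModel)
    questionnaire_path: Optional[str] = None
    amounts: PaymentAmounts = field(default_factory=PaymentAmounts)
    timing: PaymentTimingPolicy = field(default_factory=PaymentTimingPolicy)
    thresholds: FraudThresholds = field(default_factory=FraudThresholds)
    coupon_expiry_days: int = 14
    output_dir: str = "out"
    rng_seed: int = 0


def load_run_config(path: str) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    sim = raw.get("simulation", {})
    fraud = sim.pop("fraud", None)
    for key, val in sim.items():
        if not hasattr(cfg.simulation, key):
            raise ConfigError(f"unknown simulation key {key!r}")
        setattr(cfg.simulation, key, val)
    if fraud:
        cfg.simulation.fraud = FraudConfig(**fraud)
    for key, val in raw.get("population", {}).items():
        if not hasattr(cfg.population, key):
            raise ConfigError(f"unknown population key {key!r}")
        if key == "degree_distribution":
            val = tuple(val)
        setattr(cfg.population, key, val)
    pol = raw.get("policy", {})
    if "amounts" in pol:
        cfg.amounts = PaymentAmounts(**pol["amounts"])
    if "interview_delay_minutes" in pol:
        cfg.timing.initial_delay = int(pol["interview_delay_minutes"]) * MINUTE
    if "mitigated_delay_days" in pol:
        cfg.timing.mitigated_delay = int(pol["mitigated_delay_days"]) * DAY
    if "min_redemption_latency" in pol:
        cfg.thresholds.min_latency = int(pol["min_redemption_latency"])
    cfg.coupon_expiry_days = int(raw.get("coupon_expiry_days", cfg.coupon_expiry_days))
    cfg.questionnaire_path = raw.get("questionnaire")
    if cfg.questionnaire_path and not os.path.exists(cfg.questionnaire_path):
        raise ConfigError(f"questionnaire file not found: {cfg.questionnaire_path}")
    cfg.output_dir = raw.get("output_dir", cfg.output_dir)
    cfg.rng_seed = int(raw.get("rng_seed", cfg.rng_seed))
    cfg.simulation.rng_seed = cfg.rng_seed
    return cfg
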