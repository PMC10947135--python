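"""Configuration loading, shipped defaults, fixtures and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from . import dgp as tv_dgp
from .dgp import (
    DGPCoefficients,
    ScenarioSpec,
    generate_complete_panel,
)
from .panel import Panel


def _load_defaults() -> dict:
    text = resources.files("tvmiss").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_coefficients(outcome_dist: str = "normal",
                         misspec: str = "none") -> DGPCoefficients:
    """Shipped calibrated coefficients for one simulation cell."""
    raw = _load_defaults()
    co = raw["coefficients"]
    base, conf, trt, out, mis = (co["baseline"], co["confounder"],
                                 co["treatment"], co["outcome"], co["missingness"])
    kwargs = dict(
        b_bin_prev=base["b_bin_prev"], b_cont_a=base["b_cont_a"],
        b_cont_b=base["b_cont_b"], b_cont_lo=base["b_cont_lo"],
        b_cont_hi=base["b_cont_hi"],
        x0_sd=conf["x0_sd"], x_intercept=conf["intercept"],
        x_on_a_lag=conf["a_lag"], x_on_x_lag=conf["x_lag"],
        x_on_b_std=conf["b_std"], x_on_b_bin=conf["b_bin"], x_sd=conf["sd"],
        a_intercept=trt["intercept"], a_on_a_lag=trt["a_lag"], a_on_x=trt["x"],
        a_on_y_lag=trt["y_lag"], a_on_b_std=trt["b_std"], a_on_b_bin=trt["b_bin"],
        y_intercept=out["intercept"], y_on_a=out["a"], y_on_a_lag=out["a_lag"],
        y_on_x=out["x"], y_on_y_lag=out["y_lag"], y_on_b_std=out["b_std"],
        y_on_b_bin=out["b_bin"], y_sigma=out["sigma"],
        m_on_a_lag=mis["a_lag"], m_on_x_lag=mis["x_lag"], m_on_y_lag=mis["y_lag"],
        m_on_b_std=mis["b_std"], m_on_b_bin=mis["b_bin"],
        outcome_dist=outcome_dist,
        target_ate=raw["target_ate"][outcome_dist],
    )
    if outcome_dist != "normal":
        sk = raw["skew_effects"]
        kwargs.update(y_on_a=sk["y_on_a"], y_on_a_lag=sk["y_on_a_lag"],
                      x_on_a_lag=sk["x_on_a_lag"])
    if misspec != "none":
        om = raw["misspec_interaction"][misspec]
        kwargs.update(y_on_bx=om["outcome"], r_on_bx=om["missingness"])
    return DGPCoefficients(**kwargs)


# ----------------------------------------------------------------------
# user configuration files
# ----------------------------------------------------------------------

_SCENARIO_KEYS = {
    "name", "pattern", "level", "outcome_dist", "misspec",
    "n", "n_reps", "m_imputations", "base_seed", "n_burnin",
}


def load_config(path) -> Tuple[List[ScenarioSpec], DGPCoefficients]:
    """Read a YAML/JSON run configuration.

    Schema: a ``scenarios`` list (keys mirroring :class:`ScenarioSpec`) and
    an optional ``coefficients`` block overriding individual
    :class:`DGPCoefficients` fields.  Unknown keys are rejected with the
    offending name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown_top = set(raw) - {"scenarios", "coefficients"}
    if unknown_top:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown_top)}")
    scen_raw = raw.get("scenarios", [])
    if not isinstance(scen_raw, list) or not scen_raw:
        raise ValueError("config must contain a non-empty 'scenarios' list")
    specs = []
    for i, item in enumerate(scen_raw):
        unknown = set(item) - _SCENARIO_KEYS
        if unknown:
            raise ValueError(
                f"scenario {i}: unknown keys {sorted(unknown)}; "
                f"allowed: {sorted(_SCENARIO_KEYS)}"
            )
        try:
            specs.append(ScenarioSpec(**item))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"scenario {i}: {exc}") from exc

    outcome_dist = specs[0].outcome_dist
    misspec = specs[0].misspec
    coeffs = default_coefficients(outcome_dist, misspec)
    overrides = raw.get("coefficients") or {}
    if overrides:
        valid = set(DGPCoefficients.__dataclass_fields__)
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown coefficient keys: {sorted(unknown)}")
        from dataclasses import replace
        coeffs = replace(coeffs, **overrides)
    return specs, coeffs


# ----------------------------------------------------------------------
# deterministic test fixtures
# ----------------------------------------------------------------------

FIXTURE_KINDS = ("complete", "table1_patient1", "table1_patient2", "dropout", "mixed")


def make_fixture(kind: str = "complete", seed: int = 7, n: int = 20) -> Panel:
    """Small deterministic panels exhibiting the canonical registry patterns.

    ``table1_patient1``: alternating single-variable intermittent gaps;
    ``table1_patient2``: both x and y missing for two consecutive visits,
    observed again afterwards; ``dropout``: absorbing missingness from
    visit 2; ``mixed``: one person of each pattern.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"fixture kind must be one of {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    while True:
        # tiny cohorts can violate the positivity band by chance; redraw
        try:
            panel = generate_complete_panel(n, default_coefficients(), rng)
            break
        except tv_dgp.PositivityError:
            continue

    def blank(i, t, which):
        if "x" in which:
            panel.r_x[i, t] = 0
            panel.x[i, t] = np.nan
        if "y" in which:
            panel.r_y[i, t] = 0
            panel.y[i, t] = np.nan

    def patient1(i):
        blank(i, 1, "y"); blank(i, 2, "x"); blank(i, 3, "y"); blank(i, 4, "x")

    def patient2(i):
        blank(i, 1, "xy"); blank(i, 2, "xy")  # observed again from visit 3

    def patient3(i):
        for t in (2, 3, 4):
            blank(i, t, "xy")
            panel.c[i, t] = 1

    if kind == "table1_patient1":
        patient1(0)
    elif kind == "table1_patient2":
        patient2(0)
    elif kind == "dropout":
        patient3(0)
    elif kind == "mixed":
        patient1(0); patient2(1); patient3(2)
    panel.validate()
    return panel


# ----------------------------------------------------------------------
# run manifests
# ----------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a simulation run bit-identically."""

    config_hash: str
    master_seed: int
    scenarios: List[str]
    version: str = __version__
    status: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def for_run(cls, specs: List[ScenarioSpec], master_seed: int) -> "RunManifest":
        blob = json.dumps([sorted(s.__dict__.items()) for s in specs],
                          default=str, sort_keys=True)
        digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return cls(config_hash=digest, master_seed=master_seed,
                   scenarios=[s.name for s in specs])

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
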