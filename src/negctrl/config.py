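"""Scenario configuration from YAML/JSON documents.

A scenario document mirrors the parameter types::

    design: binary            # or continuous
    structural: {beta1: 0.2, beta2: 0.0, gamma: 0.2, sigma_eps: 1.0}
    confounding: {rho_UE: 0.4, rho_UC: 0.4}
    error: {p_E: 0.1, p_C: 0.5}          # binary design
    # error: {icc_E: 0.7, icc_C: 1.0}    # continuous design
    n: 10000
    reps: 2000
    seed: 1

Unknown keys raise, so typos do not silently fall back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .parameters import (
    BinaryErrorSpec,
    ConfoundingStructure,
    ContinuousErrorSpec,
    StructuralParams,
    ValidationError,
)

__all__ = ["Scenario", "scenario_from_dict", "load_scenario"]


@dataclass(frozen=True)
class Scenario:
    """A parsed scenario configuration."""

    design: str
    sp: StructuralParams
    conf: ConfoundingStructure
    err: ContinuousErrorSpec | BinaryErrorSpec
    n: int = 10_000
    reps: int = 2_000
    seed: int = 0

    def provenance(self) -> dict:
        """Flat record of every parameter, for echoing into outputs."""
        rec = {
            "design": self.design,
            "beta1": self.sp.beta1,
            "beta2": self.sp.beta2,
            "gamma": self.sp.gamma,
            "sigma_eps": self.sp.sigma_eps,
            "rho_UE": self.conf.rho_UE,
            "rho_UC": self.conf.rho_UC,
            "rho_EC": self.conf.rho_EC,
            "n": self.n,
            "reps": self.reps,
            "seed": self.seed,
        }
        if isinstance(self.err, BinaryErrorSpec):
            rec.update(p_E=self.err.p_E, p_C=self.err.p_C, quantile_cut=self.err.quantile_cut)
        else:
            rec.update(icc_E=self.err.icc_E, icc_C=self.err.icc_C)
        return rec


def _pick(d: dict, allowed: set[str], what: str) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown {what} keys: {sorted(unknown)}")
    return d


def scenario_from_dict(doc: dict) -> Scenario:
    """Build a :class:`Scenario` from a parsed configuration mapping."""
    doc = _pick(
        dict(doc),
        {"design", "structural", "confounding", "error", "n", "reps", "seed"},
        "scenario",
    )
    design = doc.get("design", "continuous")
    if design not in ("continuous", "binary"):
        raise ValidationError(f"design must be 'continuous' or 'binary', got {design!r}")
    sp = StructuralParams(
        **_pick(dict(doc.get("structural", {})), {"beta1", "beta2", "gamma", "sigma_eps"},
                "structural")
    )
    conf = ConfoundingStructure(
        **_pick(dict(doc.get("confounding", {})), {"rho_UE", "rho_UC"}, "confounding")
    )
    err_doc = dict(doc.get("error", {}))
    if design == "binary":
        err: ContinuousErrorSpec | BinaryErrorSpec = BinaryErrorSpec(
            **_pick(err_doc, {"p_E", "p_C", "quantile_cut"}, "error")
        )
    else:
        err = ContinuousErrorSpec(
            **_pick(err_doc, {"icc_E", "icc_C", "sigma2_true"}, "error")
        )
    return Scenario(
        design=design, sp=sp, conf=conf, err=err,
        n=int(doc.get("n", 10_000)),
        reps=int(doc.get("reps", 2_000)),
        seed=int(doc.get("seed", 0)),
    )


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML or JSON file (by extension)."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValidationError(f"scenario file {path} must contain a mapping")
    return scenario_from_dict(doc)
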