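"""Complete simulation parameter sets and name-based parameter access."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Optional

from .currents import PassiveParams, PumpParams
from .errors import ArgumentError, SchemaError
from .excitation import StoreKinetics
from .schedules import GclDecay, KappaRamp, Schedule

__all__ = ["ParameterSet", "get_param", "set_param", "set_params"]


@dataclass(frozen=True)
class ParameterSet:
    """Everything a simulation needs: one column of the parameter tables.

    V0 is the pre-excitation resting PD the trace starts from (mV); for
    depolarized pump-off cells it is a measured value, not the model's own
    zero-current root.  ``post_pd`` keeps the printed post-excitation PD for
    reference where one exists.
    """

    label: str
    kinetics: StoreKinetics
    passive: PassiveParams
    pump: Optional[PumpParams] = None
    schedule: Schedule = Schedule()
    V0: float = -234.0
    post_pd: Optional[float] = None

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    # ---- lossless serialization -------------------------------------
    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "kinetics": dataclasses.asdict(self.kinetics),
            "passive": dataclasses.asdict(self.passive),
            "pump": None if self.pump is None else dataclasses.asdict(self.pump),
            "schedule": {
                "kappa_ramp": (None if self.schedule.kappa_ramp is None
                               else dataclasses.asdict(self.schedule.kappa_ramp)),
                "gcl_decay": (None if self.schedule.gcl_decay is None
                              else dataclasses.asdict(self.schedule.gcl_decay)),
            },
            "V0": self.V0,
            "post_pd": self.post_pd,
        }
        d["kinetics"]["dCa_window"] = list(self.kinetics.dCa_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        allowed = {"label", "kinetics", "passive", "pump", "schedule", "V0",
                   "post_pd"}
        unknown = set(d) - allowed
        if unknown:
            raise SchemaError(f"unknown field(s): {sorted(unknown)}")
        missing = {"label", "kinetics", "passive", "V0"} - set(d)
        if missing:
            raise SchemaError(f"missing required field(s): {sorted(missing)}")

        def build(klass, payload, what):
            if payload is None:
                return None
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(payload) - names
            if bad:
                raise SchemaError(f"unknown {what} field(s): {sorted(bad)}")
            return klass(**payload)

        kin = dict(d["kinetics"])
        if "dCa_window" in kin:
            kin["dCa_window"] = tuple(kin["dCa_window"])
        sched_d = d.get("schedule") or {}
        bad = set(sched_d) - {"kappa_ramp", "gcl_decay"}
        if bad:
            raise SchemaError(f"unknown schedule field(s): {sorted(bad)}")
        schedule = Schedule(
            kappa_ramp=build(KappaRamp, sched_d.get("kappa_ramp"), "kappa_ramp"),
            gcl_decay=build(GclDecay, sched_d.get("gcl_decay"), "gcl_decay"))
        return cls(label=d["label"],
                   kinetics=build(StoreKinetics, kin, "kinetics"),
                   passive=build(PassiveParams, d["passive"], "passive"),
                   pump=build(PumpParams, d.get("pump"), "pump"),
                   schedule=schedule, V0=float(d["V0"]),
                   post_pd=d.get("post_pd"))

    def content_hash(self) -> str:
        """Stable hash of the resolved parameter values (provenance logging)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# Mapping from flat fit/override names to (component, field).
_PARAM_PATHS = {
    # store kinetics
    "p1_prime": ("kinetics", "p1_prime"), "p2_prime": ("kinetics", "p2_prime"),
    "k1": ("kinetics", "k1"), "k_m1": ("kinetics", "k_m1"),
    "k2_prime": ("kinetics", "k2_prime"), "k_m2": ("kinetics", "k_m2"),
    "k3_prime": ("kinetics", "k3_prime"), "k_m3": ("kinetics", "k_m3"),
    "gamma0": ("kinetics", "gamma0"), "gamma1": ("kinetics", "gamma1"),
    "nu_r": ("kinetics", "nu_r"), "C0": ("kinetics", "C0"),
    "I0": ("kinetics", "I0"), "ip3_decay": ("kinetics", "ip3_decay"),
    "dCa": ("kinetics", "dCa"), "hill_n": ("kinetics", "hill_n"),
    # passive / chloride
    "G_Cl_max": ("passive", "G_Cl_max"), "k_a": ("passive", "k_a"),
    "k_i": ("passive", "k_i"), "G_bkg": ("passive", "G_bkg"),
    "E_bkg": ("passive", "E_bkg"), "G_Ca": ("passive", "G_Ca"),
    "Cm": ("passive", "Cm"), "NK_PK": ("passive", "NK_PK"),
    "V50_plus": ("passive", "V50_plus"), "V50_minus": ("passive", "V50_minus"),
    "K_cyt": ("passive", "K_cyt"), "K_out": ("passive", "K_out"),
    "Cl_cyt": ("passive", "Cl_cyt"), "Cl_out": ("passive", "Cl_out"),
    # pump
    "kappa_oi": ("pump", "kappa_oi"), "kappa_io": ("pump", "kappa_io"),
    "kio0": ("pump", "kio0"), "koi0": ("pump", "koi0"),
    # ramp endpoints (fittable schedule knobs)
    "kappa_end": ("schedule.kappa_ramp", "end_value"),
    "kappa_t_start": ("schedule.kappa_ramp", "t_start"),
    "kappa_t_stop": ("schedule.kappa_ramp", "t_stop"),
    # top level
    "V0": (None, "V0"),
}


def _component(ps: ParameterSet, comp: str):
    if comp == "schedule.kappa_ramp":
        if ps.schedule.kappa_ramp is None:
            raise ArgumentError("parameter set has no kappa_oi ramp schedule")
        return ps.schedule.kappa_ramp
    return getattr(ps, comp)


def get_param(ps: ParameterSet, name: str) -> float:
    """Read a parameter by flat name (see ``set_param``)."""
    if name not in _PARAM_PATHS:
        raise ArgumentError(f"unknown parameter {name!r}; "
                            f"known: {sorted(_PARAM_PATHS)}")
    comp, fld = _PARAM_PATHS[name]
    if comp is None:
        return getattr(ps, fld)
    obj = _component(ps, comp)
    if obj is None:
        raise ArgumentError(f"parameter {name!r} targets the pump, "
                            f"but {ps.label!r} has no pump")
    return getattr(obj, fld)


def set_param(ps: ParameterSet, name: str, value) -> ParameterSet:
    """Return a copy of ``ps`` with one named parameter replaced."""
    if name not in _PARAM_PATHS:
        raise ArgumentError(f"unknown parameter {name!r}; "
                            f"known: {sorted(_PARAM_PATHS)}")
    comp, fld = _PARAM_PATHS[name]
    if comp is None:
        return ps.replace(**{fld: value})
    if comp == "schedule.kappa_ramp":
        ramp = _component(ps, comp)
        new_ramp = dataclasses.replace(ramp, **{fld: value})
        return ps.replace(schedule=dataclasses.replace(
            ps.schedule, kappa_ramp=new_ramp))
    obj = _component(ps, comp)
    if obj is None:
        raise ArgumentError(f"parameter {name!r} targets the pump, "
                            f"but {ps.label!r} has no pump")
    new_obj = dataclasses.replace(obj, **{fld: value})
    if comp == "pump" and fld == "kappa_oi" and ps.schedule.kappa_ramp is not None:
        # keep the ramp anchored at the (possibly new) starting kappa_oi
        sched = dataclasses.replace(
            ps.schedule, kappa_ramp=dataclasses.replace(
                ps.schedule.kappa_ramp, start_value=value))
        return ps.replace(pump=new_obj, schedule=sched)
    return ps.replace(**{comp: new_obj})


def set_params(ps: ParameterSet, **named) -> ParameterSet:
    for name, value in named.items():
        ps = set_param(ps, name, value)
    return ps
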