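"""TOML configuration round-trip for the model parameter tables.

Sections: [remodeler] (RemodelerParams), [sequence] (MappingRules),
[dynamics] (IntegratorConfig + schedule choice).  Keys match the dataclass
field names; eps_lobes is spelled per state (eps_lobes_apo, ...).
"""

from __future__ import annotations

import dataclasses
import tomllib

from .dynamics import IntegratorConfig, Schedule
from .model import ChemicalState, RemodelerParams
from .sequences import MappingRules

__all__ = ["load_config", "save_config", "default_config"]


def default_config() -> dict:
    return {
        "remodeler": RemodelerParams(),
        "sequence": MappingRules(),
        "dynamics": IntegratorConfig(),
        "schedule": Schedule.default(),
    }


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return f'"{v}"'


def save_config(cfg: dict, path) -> None:
    rem = cfg["remodeler"]
    rules = cfg["sequence"]
    dyn = cfg["dynamics"]
    sched = cfg["schedule"]
    lines = ["[remodeler]"]
    lines.append(f"eps_lobe_dna = [{rem.eps_lobe_dna[0]!r}, {rem.eps_lobe_dna[1]!r}]")
    for state in ChemicalState:
        lines.append(f"eps_lobes_{state.value} = {rem.eps_lobes[state]!r}")
    for name in (
        "adp_lobe2_factor", "lobe1_strain", "closure_offset", "closure_barrier",
        "eps_elec", "elec_width", "wall_halfwidth", "wall_height",
    ):
        lines.append(f"{name} = {getattr(rem, name)!r}")
    lines.append("")
    lines.append("[sequence]")
    for f in dataclasses.fields(rules):
        lines.append(f"{f.name} = {_fmt(getattr(rules, f.name))}")
    lines.append("")
    lines.append("[dynamics]")
    for f in dataclasses.fields(dyn):
        lines.append(f"{f.name} = {getattr(dyn, f.name)!r}")
    phases = ", ".join(f'["{c.value}", {d!r}]' for c, d in sched.phases)
    lines.append(f"schedule = [{phases}]")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    rem_raw = dict(raw.get("remodeler", {}))
    eps_lobes = {
        state: rem_raw.pop(f"eps_lobes_{state.value}", RemodelerParams().eps_lobes[state])
        for state in ChemicalState
    }
    if "eps_lobe_dna" in rem_raw:
        rem_raw["eps_lobe_dna"] = tuple(rem_raw["eps_lobe_dna"])
    rem = RemodelerParams(eps_lobes=eps_lobes, **rem_raw)
    rules = MappingRules(**raw.get("sequence", {}))
    dyn_raw = dict(raw.get("dynamics", {}))
    sched_raw = dyn_raw.pop("schedule", None)
    dyn = IntegratorConfig(**dyn_raw)
    if sched_raw is None:
        sched = Schedule.default()
    else:
        sched = Schedule(tuple((ChemicalState(c), float(d)) for c, d in sched_raw))
    return {"remodeler": rem, "sequence": rules, "dynamics": dyn, "schedule": sched}
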