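"""Run configuration: chain roles, residue ranges, cutoffs, thresholds.

Chain identities in deposited coordinate files are arbitrary, so the mapping
from file chains to roles (peptide / heavy / light / receptor) is always
supplied by configuration, never guessed.  The defaults encode the epitope
bookkeeping used throughout the package: the EGFR 287–302 cystine loop as
the epitope, the well-ordered 293–302 strand pair as the superposition
anchor, and the four-ectodomain-domain layout (I 1–164, II 165–310,
III 311–480, IV 481–618).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .accessibility import DEFAULT_DOMAIN_MAP, DomainMap
from .contacts import CdrMap, ContactCutoffs
from .sasa import SasaParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    chain_roles: dict[str, str] = field(default_factory=dict)  # role -> chain id
    epitope_range: tuple[int, int] = (287, 302)
    hairpin_range: tuple[int, int] = (293, 302)
    cdr_map: CdrMap = field(default_factory=CdrMap)
    domain_map: DomainMap = field(default_factory=lambda: DomainMap(dict(DEFAULT_DOMAIN_MAP.ranges)))
    cutoffs: ContactCutoffs = field(default_factory=ContactCutoffs)
    sasa_params: SasaParams = field(default_factory=SasaParams)
    clash_tolerance: float = 0.4
    accessible_max: int = 10
    inaccessible_min: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("epitope_range", self.epitope_range),
                               ("hairpin_range", self.hairpin_range)):
            if lo > hi:
                raise ValueError(f"{name}: lo {lo} > hi {hi}")
        if self.clash_tolerance < 0:
            raise ValueError("clash_tolerance must be non-negative")
        if self.accessible_max >= self.inaccessible_min:
            raise ValueError("accessible_max must be below inaccessible_min")

    def provenance(self) -> dict:
        """Full parameter set, embedded in every report for re-runnability."""
        return {
            "chain_roles": dict(self.chain_roles),
            "epitope_range": list(self.epitope_range),
            "hairpin_range": list(self.hairpin_range),
            "cdr_map": {role: {lab: list(rng) for lab, rng in windows}
                        for role, windows in self.cdr_map.ranges.items()},
            "domain_map": {k: list(v) for k, v in self.domain_map.ranges.items()},
            "cutoffs": asdict(self.cutoffs),
            "sasa_params": {"probe_radius": self.sasa_params.probe_radius,
                            "n_sphere_points": self.sasa_params.n_sphere_points,
                            "radii_set": self.sasa_params.radii_set},
            "clash_tolerance": self.clash_tolerance,
            "accessibility_thresholds": [self.accessible_max, self.inaccessible_min],
            "seed": self.seed,
        }


def _parse_range(v) -> tuple[int, int]:
    if isinstance(v, str):
        lo, hi = v.replace("-", ":").split(":")
        return int(lo), int(hi)
    lo, hi = v
    return int(lo), int(hi)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file with per-key overrides.

    Recognised keys mirror the RunConfig fields; ranges may be written
    ``"lo:hi"`` or ``[lo, hi]``.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)

    kwargs: dict = {}
    if "chain_roles" in data:
        kwargs["chain_roles"] = {str(k): str(v) for k, v in data["chain_roles"].items()}
    for key in ("epitope_range", "hairpin_range"):
        if key in data:
            kwargs[key] = _parse_range(data[key])
    if "cdr_map" in data:
        cm = data["cdr_map"]
        kwargs["cdr_map"] = cm if isinstance(cm, CdrMap) else CdrMap.from_dict(
            {role: [(lab, _parse_range(rng)) for lab, rng in
                    (windows.items() if isinstance(windows, dict) else windows)]
             for role, windows in cm.items()})
    if "domain_map" in data:
        dm = data["domain_map"]
        kwargs["domain_map"] = dm if isinstance(dm, DomainMap) else DomainMap(
            {str(k): _parse_range(v) for k, v in dm.items()})
    if "cutoffs" in data:
        c = data["cutoffs"]
        kwargs["cutoffs"] = c if isinstance(c, ContactCutoffs) else ContactCutoffs(**c)
    if "sasa_params" in data:
        s = data["sasa_params"]
        kwargs["sasa_params"] = s if isinstance(s, SasaParams) else SasaParams(**s)
    for key in ("clash_tolerance", "accessible_max", "inaccessible_min", "seed"):
        if key in data:
            kwargs[key] = type(RunConfig.__dataclass_fields__[key].default)(data[key]) \
                if not isinstance(data[key], (int, float)) else data[key]
    return RunConfig(**kwargs)
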