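"""Run configuration: YAML in, validated settings out.

A config file declares what cannot be computed from coordinates alone:
which chain is the receptor, which residue ranges are common to all
compared structures, which het codes are the ligand, the contact
criterion, and the Ballesteros-Weinstein scheme. Every key has a shipped
default (the beta-2 adrenergic receptor scheme, csu_like contacts), so a
minimal run needs no file at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotation import BWScheme, beta2ar_scheme
from .contact_detection import ContactCriterion
from .errors import InputError


@dataclass
class RunConfig:
    receptor_chain: str | None = None          # None: keep all chains
    segments: list[tuple[str, int, int]] = field(default_factory=list)
    ligand_names: set[str] = field(default_factory=set)
    altloc_policy: str = "highest_occupancy"
    criterion: ContactCriterion = field(default_factory=ContactCriterion)
    scheme: BWScheme = field(default_factory=beta2ar_scheme)
    k_high: float = 1.0      # high-centrality cutoff multiplier
    k_delta: float = 2.5     # activation / ligand delta multiplier
    seed: int = 0

    def __post_init__(self):
        if self.k_high < 0 or self.k_delta < 0:
            raise ValueError("k multipliers must be >= 0")


def load_config(path: str | None) -> RunConfig:
    """Build a RunConfig from a YAML file; missing file -> InputError."""
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise InputError(f"config file not found: {path}")
    with open(p) as fh:
        raw = yaml.safe_load(fh) or {}

    crit_raw = raw.get("criterion", {})
    crit = ContactCriterion(
        mode=crit_raw.get("mode", "csu_like"),
        probe_radius=float(crit_raw.get("probe_radius", 1.4)),
        cutoff=float(crit_raw.get("cutoff", 4.5)),
    )
    if "vdw_radii" in crit_raw:
        crit.vdw_radii.update({k.upper(): float(v) for k, v in crit_raw["vdw_radii"].items()})

    scheme_raw = raw.get("bw_scheme")
    if scheme_raw is None:
        scheme = beta2ar_scheme()
    else:
        scheme = BWScheme(
            anchors={int(k): int(v) for k, v in scheme_raw["anchors"].items()},
            tm_ranges={int(k): (int(v[0]), int(v[1]))
                       for k, v in scheme_raw["tm_ranges"].items()},
            regions=[(label, (int(lo), int(hi)))
                     for label, (lo, hi) in scheme_raw.get("regions", [])],
        )

    return RunConfig(
        receptor_chain=raw.get("receptor_chain"),
        segments=[(str(c), int(lo), int(hi)) for c, lo, hi in raw.get("segments", [])],
        ligand_names={str(x).upper() for x in raw.get("ligand_names", [])},
        altloc_policy=raw.get("altloc_policy", "highest_occupancy"),
        criterion=crit,
        scheme=scheme,
        k_high=float(raw.get("k_high", 1.0)),
        k_delta=float(raw.get("k_delta", 2.5)),
        seed=int(raw.get("seed", 0)),
    )
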