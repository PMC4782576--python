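"""Constitutive methylation-state sets across the fetal ground state.

A region is constitutively unmethylated (cu) when its average beta lies
below the sample-specific lower threshold L in every fetal sample, and a
gene body constitutively methylated (cm) when it lies above the upper
threshold U in every fetal sample.  Both inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .preprocess import BetaMixtureFit

STATES = ("unmethylated", "intermediate", "methylated")
SET_KINDS = ("cu_GP", "cu_CGI", "cm_GB")


def call_region_state(beta: float, L: float, U: float) -> str:
    """Three-state call for one region value against sample thresholds.

    beta < L -> unmethylated; beta > U -> methylated; otherwise
    intermediate (boundaries are intermediate: "less than" is strict).
    """
    if not 0 < L < U < 1:
        raise ValueError(f"need 0 < L < U < 1, got L={L}, U={U}")
    if not 0 <= beta <= 1:
        raise ValueError(f"beta {beta} outside [0, 1]")
    if beta < L:
        return "unmethylated"
    if beta > U:
        return "methylated"
    return "intermediate"


@dataclass
class ConstitutiveSet:
    """Region ids meeting the defining state in every fetal sample."""

    set_kind: str
    members: list[str]
    samples: list[str]
    thresholds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.set_kind not in SET_KINDS:
            raise ValueError(f"set_kind must be one of {SET_KINDS}")

    def __contains__(self, region_id: str) -> bool:
        return region_id in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


def constitutive_set(
    region_betas: pd.DataFrame,
    fits: Mapping[str, BetaMixtureFit],
    set_kind: str,
) -> ConstitutiveSet:
    """Build a cu/cm set from fetal region betas and per-sample mixture fits.

    ``region_betas`` is regions x fetal samples.  cu sets require the
    unmethylated call in every sample; cm_GB requires the methylated call in
    every sample.  Regions with any missing value are excluded.
    """
    if set_kind not in SET_KINDS:
        raise ValueError(f"set_kind must be one of {SET_KINDS}")
    missing = [s for s in region_betas.columns if s not in fits]
    if missing:
        raise ValueError(f"missing beta-mixture fit for sample(s): {missing}")
    want = "methylated" if set_kind == "cm_GB" else "unmethylated"

    keep = pd.Series(True, index=region_betas.index)
    thresholds = {}
    for sample in region_betas.columns:
        fit = fits[sample]
        if fit.lower is None or fit.upper is None:
            raise ValueError(f"fit for sample {sample!r} has no thresholds")
        L, U = float(fit.lower), float(fit.upper)
        thresholds[sample] = (L, U)
        col = region_betas[sample]
        if want == "unmethylated":
            keep &= col < L
        else:
            keep &= col > U
    members = sorted(region_betas.index[keep.fillna(False)])
    return ConstitutiveSet(
        set_kind=set_kind,
        members=[str(r) for r in members],
        samples=list(region_betas.columns),
        thresholds=thresholds,
    )


def write_constitutive_set(cs: ConstitutiveSet, path: str | Path) -> None:
    """One-column id list with a YAML provenance header in '#' comments."""
    header = {
        "set_kind": cs.set_kind,
        "n_members": len(cs.members),
        "samples": cs.samples,
        "thresholds": {s: [float(l), float(u)] for s, (l, u) in cs.thresholds.items()},
    }
    with open(path, "w") as fh:
        for line in yaml.safe_dump(header, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        for region_id in cs.members:
            fh.write(region_id + "\n")


def read_constitutive_set(path: str | Path) -> ConstitutiveSet:
    header_lines, members = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                header_lines.append(line[2:])
            elif line.strip():
                members.append(line.strip())
    meta = yaml.safe_load("\n".join(header_lines)) or {}
    return ConstitutiveSet(
        set_kind=meta.get("set_kind", "cu_GP"),
        members=members,
        samples=meta.get("samples", []),
        thresholds={s: tuple(v) for s, v in meta.get("thresholds", {}).items()},
    )
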