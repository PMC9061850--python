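"""Docking-restraint selection and export from NMR interface maps.

Active residues for data-driven docking are selected from the per-residue
profiles produced by the binding analysis: on the peptide (ligand) side a
residue is active when its CSP is above average at a majority of
titration ratios; on the chaperone (receptor) side when it loses more
than half of its signal intensity next to the paramagnetic tag.  The
resulting per-chain lists are exported either as plain chain:residue
lines or as ambiguous-interaction-restraint (AIR) stanzas in a TBL-like
plain-text dialect, ready for an external docking engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .binding import ResidueProfile

__all__ = [
    "RestraintSet",
    "select_ligand_actives",
    "select_receptor_actives",
    "export_restraints",
    "read_restraints",
]


@dataclass
class RestraintSet:
    """Per-chain active-residue lists with selection provenance."""

    chains: dict[str, list[int]] = field(default_factory=dict)
    provenance: dict[tuple[str, int], str] = field(default_factory=dict)
    label: str = "monomer-dock"

    def __post_init__(self) -> None:
        for chain, ids in self.chains.items():
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate residue ids on chain {chain!r}")
            self.chains[chain] = sorted(ids)

    def total(self) -> int:
        return sum(len(v) for v in self.chains.values())


def select_ligand_actives(
    profiles_by_ratio: Mapping[float, Sequence[ResidueProfile]],
    majority_frac: float = 0.5,
    chain: str = "A",
    label: str = "monomer-dock",
) -> RestraintSet:
    """Residues with above-average CSP at most titration ratios.

    A residue is active when its ``csp_above_avg`` flag is set in
    strictly more than ``majority_frac`` of the supplied ratios.
    """
    if len(profiles_by_ratio) < 2:
        raise ValueError("need profiles from at least two titration ratios")
    counts: dict[int, int] = {}
    seen: dict[int, int] = {}
    for ratio in sorted(profiles_by_ratio):
        for p in profiles_by_ratio[ratio]:
            seen[p.residue_id] = seen.get(p.residue_id, 0) + 1
            if p.csp_above_avg:
                counts[p.residue_id] = counts.get(p.residue_id, 0) + 1
    n_ratios = len(profiles_by_ratio)
    active = sorted(
        res for res, c in counts.items() if c / n_ratios > majority_frac
    )
    if not seen:
        warnings.warn("empty profiles: no ligand actives selected", stacklevel=2)
    rset = RestraintSet(chains={chain: active} if active else {}, label=label)
    for res in active:
        rset.provenance[(chain, res)] = (
            f"csp_above_avg in {counts[res]}/{n_ratios} ratios "
            f"(> {majority_frac:g})"
        )
    return rset


def select_receptor_actives(
    pre_profiles: Mapping[str, Sequence[ResidueProfile]],
    loss_threshold: float = 0.5,
    label: str = "monomer-dock",
) -> RestraintSet:
    """Residues with more than ``loss_threshold`` paramagnetic intensity
    loss, kept separate per chain (alpha, beta, beta')."""
    chains: dict[str, list[int]] = {}
    prov: dict[tuple[str, int], str] = {}
    for chain, profiles in pre_profiles.items():
        active = sorted(
            p.residue_id for p in profiles
            if (1.0 - p.pre_ratio) > loss_threshold
        )
        if not profiles:
            warnings.warn(f"chain {chain!r} has no measurable residues", stacklevel=2)
        if active:
            chains[chain] = active
            for res in active:
                prov[(chain, res)] = f"PRE loss > {loss_threshold:g}"
    rset = RestraintSet(chains=chains, label=label)
    rset.provenance = prov
    return rset


def export_restraints(rset: RestraintSet, style: str = "plain") -> str:
    """Serialize a restraint set; byte-deterministic.

    ``plain``: one ``CHAIN: id,id,...`` line per non-empty chain.
    ``air``: one ambiguous-interaction stanza per active residue,
    restraining it to any active residue on any other chain, in a
    TBL-like dialect.
    """
    if style == "plain":
        lines = [
            f"{chain}: {','.join(str(i) for i in rset.chains[chain])}"
            for chain in sorted(rset.chains)
            if rset.chains[chain]
        ]
        return "\n".join(lines) + ("\n" if lines else "")
    if style == "air":
        stanzas = []
        for chain in sorted(rset.chains):
            partners = [c for c in sorted(rset.chains) if c != chain]
            targets = [
                f"(resid {j} and segid {p})"
                for p in partners for j in rset.chains[p]
            ]
            target_expr = " or ".join(targets) if targets else "(all)"
            for i in rset.chains[chain]:
                stanzas.append(
                    f"assign (resid {i} and segid {chain}) "
                    f"({target_expr}) 2.0 2.0 0.0"
                )
        return "\n".join(stanzas) + ("\n" if stanzas else "")
    raise ValueError(f"unknown restraint style {style!r}")


def read_restraints(text: str, label: str = "monomer-dock") -> RestraintSet:
    """Parse the plain chain:residue format back into a RestraintSet."""
    chains: dict[str, list[int]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            chain, ids = line.split(":", maxsplit=1)
            chains[chain.strip()] = [int(x) for x in ids.split(",") if x.strip()]
        except ValueError as exc:
            raise ValueError(f"malformed restraint line {lineno}: {line!r}") from exc
    return RestraintSet(chains=chains, label=label)
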