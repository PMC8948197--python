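"""Mass-action flux computation from expression profiles.

Every concentration is a surrogate built from linear-scale expression
values (TPM or comparable): the concentration of a species is the
product of its constituent genes' expression (constant species keep
their declared value regardless of the sample).  A reaction's flux is
mass action over its activating participants, attenuated divisively by
inhibitory participants:

    flux(R) = k_R * prod c(act) / prod (1 + c(inh))

with activating roles {e, g, s, tr_a} and inhibitory roles {i, tr_r}.
A pathway's flux is the mean reaction flux over its reactions minus the
mean *base* flux of its crosstalk pathways (one level only — the
subtracted term never itself subtracts crosstalk, which keeps the
recursive definition well-founded).  Crosstalk subtraction may make a
pathway flux negative; negative values are reported as-is.

Genes present in the network but absent from a profile contribute the
``missing_floor`` concentration (default 0, silencing reactions that
require them); each such gene is logged once.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from pathflux.network import (
    ACTIVATING_ROLES,
    INHIBITORY_ROLES,
    KnowledgeNetwork,
    Pathway,
    Reaction,
    Species,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A species concentration is undefined for the given network."""


@dataclass
class ExpressionProfile:
    """One sample's gene abundances on the linear TPM scale."""

    sample_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"profile {self.sample_id!r}: gene {g!r} has invalid "
                    f"abundance {v!r} (must be finite and >= 0)"
                )


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance matrix, backed by a pandas DataFrame."""

    data: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups)}")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("expression values must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def profile(self, sample_id: str) -> ExpressionProfile:
        return ExpressionProfile(
            sample_id, self.data[sample_id].astype(float).to_dict()
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
        if df.columns[0] != "gene_id":
            raise ValueError(
                f"{path}: first column must be 'gene_id', got {df.columns[0]!r}"
            )
        return cls(df.set_index("gene_id").astype(float))

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class FluxMatrix:
    """Sample-by-pathway flux values with each pathway's class label."""

    data: pd.DataFrame  # index: sample ids, columns: pathway ids
    klass_of: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path, klass_path: str | Path | None = None) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
        if klass_path is not None:
            pd.DataFrame(
                {"pathway_id": list(self.data.columns),
                 "klass": [self.klass_of[p] for p in self.data.columns]}
            ).to_csv(klass_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, klass_path: str | Path | None = None) -> "FluxMatrix":
        df = pd.read_csv(
            path, sep="\t", dtype={0: str}, float_precision="round_trip"
        ).set_index("sample_id")
        klass_of: dict[str, str] = {}
        if klass_path is not None:
            km = pd.read_csv(klass_path, sep="\t", dtype=str)
            klass_of = dict(zip(km["pathway_id"], km["klass"]))
        return cls(df.astype(float), klass_of)


def _gene_concentration(
    gene_id: str,
    profile_values: Mapping[str, float],
    missing_floor: float,
    missing_seen: set[str] | None = None,
) -> float:
    if gene_id in profile_values:
        return float(profile_values[gene_id])
    if missing_seen is not None and gene_id not in missing_seen:
        missing_seen.add(gene_id)
        logger.info(
            "gene %r absent from profile; using floor %g", gene_id, missing_floor
        )
    return missing_floor


def species_concentration(
    profile: ExpressionProfile,
    sp: Species,
    missing_floor: float = 0.0,
) -> float:
    """Concentration of a species under one expression profile.

    Constant species return their declared value.  Otherwise the
    concentration is the product of the constituent genes' expression;
    genes missing from the profile contribute ``missing_floor``.
    """
    if sp.is_constant:
        return float(sp.constant_value)
    if not sp.constituents:
        raise ConfigurationError(
            f"species {sp.id!r} has no constituents and is not constant; "
            "its concentration is undefined"
        )
    seen: set[str] = set()
    out = 1.0
    for g in sorted(sp.constituents):
        out *= _gene_concentration(g, profile.values, missing_floor, seen)
    return out


def _participant_concentration(
    species_id: str,
    profile: ExpressionProfile,
    net: KnowledgeNetwork,
    missing_floor: float,
) -> float:
    if species_id in net.species:
        return species_concentration(
            profile, net.species[species_id], missing_floor
        )
    # bare gene participant (role "g" in transcription reactions)
    return _gene_concentration(species_id, profile.values, missing_floor, set())


def reaction_flux(
    r: Reaction,
    profile: ExpressionProfile,
    net: KnowledgeNetwork,
    missing_floor: float = 0.0,
) -> float:
    """Mass-action flux of one reaction under one profile (scalar path)."""
    flux = r.rate_constant
    for p in r.participants:
        c = _participant_concentration(p.species_id, profile, net, missing_floor)
        if p.role in ACTIVATING_ROLES:
            flux *= c
        elif p.role in INHIBITORY_ROLES:
            flux /= 1.0 + c
    return flux


def _pathway_base_flux(
    p: Pathway,
    profile: ExpressionProfile,
    net: KnowledgeNetwork,
    missing_floor: float,
) -> float:
    fluxes = [
        reaction_flux(net.reactions[rid], profile, net, missing_floor)
        for rid in sorted(p.reaction_ids)
    ]
    return float(np.mean(fluxes))


def pathway_flux(
    p: Pathway,
    profile: ExpressionProfile,
    net: KnowledgeNetwork,
    missing_floor: float = 0.0,
) -> float:
    """Mean reaction flux of a pathway minus its crosstalk pathways' mean base flux."""
    base = _pathway_base_flux(p, profile, net, missing_floor)
    if not p.crosstalk_ids:
        return base
    cross = [
        _pathway_base_flux(net.pathways[q], profile, net, missing_floor)
        for q in sorted(p.crosstalk_ids)
    ]
    return base - float(np.mean(cross))


def compute_flux_matrix(
    mat: ExpressionMatrix,
    net: KnowledgeNetwork,
    missing_floor: float = 0.0,
    scale: float = 1.0,
) -> FluxMatrix:
    """Pathway flux for every sample, vectorized across samples.

    Column order follows the network's pathway order; row order follows
    the matrix's sample order.  ``scale`` applies a global multiplier
    to all expression values before any flux is computed.

    A warning reports the fraction of network genes covered by the
    matrix; zero coverage is an error.
    """
    net_genes = list(net.genes)
    if net_genes:
        present = [g for g in net_genes if g in mat.data.index]
        coverage = len(present) / len(net_genes)
        if coverage == 0.0:
            raise ValueError(
                "expression matrix covers none of the network's genes"
            )
        if coverage < 1.0:
            missing = sorted(set(net_genes) - set(present))
            warnings.warn(
                f"expression matrix covers {coverage:.1%} of network genes; "
                f"missing genes get floor {missing_floor:g}: {missing[:10]}"
                + ("..." if len(missing) > 10 else ""),
                stacklevel=2,
            )

    n = len(mat.sample_ids)
    expr = {
        g: (
            mat.data.loc[g].to_numpy(dtype=float) * scale
            if g in mat.data.index
            else np.full(n, missing_floor)
        )
        for g in net_genes
    }

    def conc(species_id: str) -> np.ndarray:
        if species_id in net.species:
            sp = net.species[species_id]
            if sp.is_constant:
                return np.full(n, float(sp.constant_value))
            if not sp.constituents:
                raise ConfigurationError(
                    f"species {sp.id!r} has no constituents and is not "
                    "constant; its concentration is undefined"
                )
            out = np.ones(n)
            for g in sorted(sp.constituents):
                out = out * expr.get(g, np.full(n, missing_floor))
            return out
        return expr.get(species_id, np.full(n, missing_floor))

    base: dict[str, np.ndarray] = {}
    rflux: dict[str, np.ndarray] = {}
    for rid, rxn in net.reactions.items():
        f = np.full(n, rxn.rate_constant)
        for p in rxn.participants:
            c = conc(p.species_id)
            if p.role in ACTIVATING_ROLES:
                f = f * c
            else:
                f = f / (1.0 + c)
        rflux[rid] = f
    for pid, pw in net.pathways.items():
        base[pid] = np.mean(
            [rflux[rid] for rid in sorted(pw.reaction_ids)], axis=0
        )

    cols: dict[str, np.ndarray] = {}
    for pid, pw in net.pathways.items():
        f = base[pid]
        if pw.crosstalk_ids:
            f = f - np.mean([base[q] for q in sorted(pw.crosstalk_ids)], axis=0)
        cols[pid] = f

    df = pd.DataFrame(cols, index=mat.sample_ids)
    df = df[[pid for pid in net.pathways]]
    klass_of = {pid: pw.klass for pid, pw in net.pathways.items()}
    return FluxMatrix(df, klass_of)
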