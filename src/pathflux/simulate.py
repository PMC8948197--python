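"""Synthetic networks and three-group expression cohorts.

The study design this module emulates is a diagnostic cohort with
three groups — malignant, benign, control — whose blood transcriptomes
differ by a multiplicative up-shift of the genes feeding designated
"driver" pathways, with effect ordering malignant >= benign >= control.
Expression is lognormal: each gene gets a lognormal baseline shared
across samples, each (gene, sample) cell gets independent lognormal
noise, and driver-pathway genes are multiplied by the group's effect
multiplier.  Multiplicative effects on a lognormal baseline propagate
predictably through the mass-action flux engine, whose reaction fluxes
are products of expression values.

Generated networks are miniature but structurally complete: every
reaction has substrate and enzyme species built from real gene
constituents, a fraction of reactions carry inhibitors, water and
oxygen appear as constant compounds, and pathways are split between
signaling transduction and energy metabolism with random crosstalk
links.  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pathflux.flux import ExpressionMatrix, FluxMatrix
from pathflux.network import (
    ACTIVATING_ROLES,
    Gene,
    KnowledgeNetwork,
    Participant,
    Pathway,
    Reaction,
    Species,
    write_network,
)
from pathflux.stats import write_labels_tsv

GROUPS = ("malignant", "benign", "control")


@dataclass(frozen=True)
class NetworkSpec:
    """Size and wiring parameters for a generated knowledge network."""

    n_genes: int = 30
    n_pathways: int = 5
    reactions_per_pathway: int = 4
    genes_per_species: int = 2
    klass_fractions: tuple[float, float] = (0.6, 0.4)  # signaling, metabolism
    crosstalk_density: float = 0.1
    inhibitor_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_pathways", "reactions_per_pathway", "genes_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("crosstalk_density", "inhibitor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.klass_fractions) - 1.0) > 1e-9:
            raise ValueError("klass_fractions must sum to 1")
        if any(f < 0 for f in self.klass_fractions):
            raise ValueError("klass_fractions must be nonnegative")
        if self.genes_per_species > self.n_genes:
            raise ValueError(
                f"genes_per_species ({self.genes_per_species}) exceeds "
                f"n_genes ({self.n_genes})"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes and effect structure for a simulated study.

    Default group sizes mirror a malignant-heavy diagnostic study
    (78 malignant / 21 benign / 40 control).  The control group is the
    reference with multiplier 1; the expected ordering of multipliers
    is malignant >= benign >= control (a violation is warned about, not
    rejected).  ``driver_pathways=None`` means the network's first
    pathway.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"malignant": 78, "benign": 21, "control": 40}
    )
    driver_pathways: tuple[str, ...] | None = None
    effect_multipliers: dict[str, float] = field(
        default_factory=lambda: {"malignant": 2.0, "benign": 1.4, "control": 1.0}
    )
    baseline_log_mean: float = 3.0  # ln scale; e^3 ~ 20 TPM typical gene
    baseline_log_sd: float = 1.0
    noise_log_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"group size for {g!r} must be >= 0")
        if sum(self.group_sizes.values()) == 0:
            raise ValueError("cohort is empty")
        for g, m in self.effect_multipliers.items():
            if m <= 0:
                raise ValueError(f"effect multiplier for {g!r} must be > 0")
        m = self.effect_multipliers
        if not (
            m.get("malignant", 1.0) >= m.get("benign", 1.0) >= m.get("control", 1.0)
        ):
            warnings.warn(
                "effect multipliers violate the expected ordering "
                "malignant >= benign >= control",
                stacklevel=2,
            )


def n_signaling_pathways(spec: NetworkSpec) -> int:
    """Rounding convention: banker's rounding of f_signaling * n, clipped
    so both classes stay representable when the fraction is interior."""
    n = int(round(spec.klass_fractions[0] * spec.n_pathways))
    return min(max(n, 0), spec.n_pathways)


def generate_network(spec: NetworkSpec) -> KnowledgeNetwork:
    """Deterministically generate a valid network of the requested sizes."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    net = KnowledgeNetwork()

    gw = len(str(spec.n_genes))
    gene_ids = [f"G{i + 1:0{gw}d}" for i in range(spec.n_genes)]
    for gid in gene_ids:
        net.genes[gid] = Gene(id=gid, name=f"gene {gid}")

    net.species["H2O"] = Species(
        id="H2O", kind="compound", is_constant=True, constant_value=1.0
    )
    net.species["O2"] = Species(
        id="O2", kind="compound", is_constant=True, constant_value=1.0
    )

    n_sig = n_signaling_pathways(spec)
    pw = len(str(spec.n_pathways))
    for p_i in range(spec.n_pathways):
        pid = f"P{p_i + 1:0{pw}d}"
        klass = (
            "signaling_transduction" if p_i < n_sig else "energy_metabolism"
        )
        reaction_ids = []
        for r_i in range(spec.reactions_per_pathway):
            rid = f"R_{pid}_{r_i + 1}"
            sub_id = f"S_{rid}_sub"
            enz_id = f"S_{rid}_enz"
            prod_id = f"S_{rid}_prod"
            net.species[sub_id] = Species(
                id=sub_id,
                kind="rna" if klass == "signaling_transduction" else "compound",
                constituents=frozenset(
                    map(str, rng.choice(gene_ids, size=spec.genes_per_species, replace=False))
                ),
            )
            net.species[enz_id] = Species(
                id=enz_id,
                kind="protein",
                constituents=frozenset(
                    map(str, rng.choice(gene_ids, size=spec.genes_per_species, replace=False))
                ),
            )
            net.species[prod_id] = Species(
                id=prod_id,
                kind="protein",
                constituents=frozenset(map(str, rng.choice(gene_ids, size=1))),
            )
            participants = [
                Participant(sub_id, "s"),
                Participant(enz_id, "e"),
            ]
            if rng.random() < 0.25:  # some reactions consume water/oxygen
                participants.append(
                    Participant("H2O" if rng.random() < 0.5 else "O2", "s")
                )
            if rng.random() < spec.inhibitor_fraction:
                inh_id = f"S_{rid}_inh"
                net.species[inh_id] = Species(
                    id=inh_id,
                    kind="protein",
                    constituents=frozenset(map(str, rng.choice(gene_ids, size=1))),
                )
                participants.append(Participant(inh_id, "i"))
            net.reactions[rid] = Reaction(
                id=rid,
                participants=tuple(participants),
                products=(prod_id,),
                rate_constant=1.0,
            )
            reaction_ids.append(rid)
        net.pathways[pid] = Pathway(
            id=pid,
            name=f"pathway {pid}",
            klass=klass,
            reaction_ids=frozenset(reaction_ids),
            crosstalk_ids=frozenset(),
        )

    pids = list(net.pathways)
    for p in pids:
        links = frozenset(
            q for q in pids if q != p and rng.random() < spec.crosstalk_density
        )
        if links:
            old = net.pathways[p]
            net.pathways[p] = dataclasses.replace(old, crosstalk_ids=links)

    net.validate()
    return net


def driver_genes(net: KnowledgeNetwork, driver_pathways) -> frozenset[str]:
    """Genes feeding a driver pathway: constituents of any species that
    participates in an activating role (not i/tr_r) in any of its
    reactions, plus bare-gene participants in such roles."""
    out: set[str] = set()
    for pid in driver_pathways:
        pw = net.pathways[pid]
        for rid in sorted(pw.reaction_ids):
            for part in net.reactions[rid].participants:
                if part.role not in ACTIVATING_ROLES:
                    continue
                if part.species_id in net.genes:
                    out.add(part.species_id)
                elif part.species_id in net.species:
                    out |= net.species[part.species_id].constituents
    return frozenset(out)


def generate_cohort(
    net: KnowledgeNetwork, spec: CohortSpec
) -> tuple[ExpressionMatrix, dict[str, str], dict]:
    """Simulate a labeled expression cohort over a network.

    Expression of gene g in a sample of group G is
    ``baseline_g * multiplier_G**[g is a driver gene] * exp(N(0, noise_log_sd))``
    with ``baseline_g ~ exp(N(baseline_log_mean, baseline_log_sd))``
    shared across samples.  Returns (matrix, sample -> group labels,
    ground-truth record).
    """
    spec.validate()
    drivers = (
        tuple(spec.driver_pathways)
        if spec.driver_pathways is not None
        else (next(iter(net.pathways)),)
    )
    unknown = [p for p in drivers if p not in net.pathways]
    if unknown:
        raise ValueError(f"driver pathways not in network: {unknown}")

    rng = np.random.default_rng(spec.seed)
    gene_ids = list(net.genes)
    n_genes = len(gene_ids)
    dgenes = driver_genes(net, drivers)
    is_driver = np.array([g in dgenes for g in gene_ids])

    baseline = np.exp(
        rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n_genes)
    )

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for group in GROUPS:
        n = spec.group_sizes.get(group, 0)
        mult = spec.effect_multipliers.get(group, 1.0)
        shift = np.where(is_driver, mult, 1.0)
        for k in range(n):
            sid = f"{group[0].upper()}{k + 1:03d}"
            noise = np.exp(rng.normal(0.0, spec.noise_log_sd, size=n_genes))
            columns.append(baseline * shift * noise)
            sample_ids.append(sid)
            labels[sid] = group

    mat = ExpressionMatrix(
        pd.DataFrame(
            np.column_stack(columns), index=gene_ids, columns=sample_ids
        )
    )
    ground_truth = {
        "driver_pathways": list(drivers),
        "driver_genes": sorted(dgenes),
        "effect_multipliers": {g: spec.effect_multipliers.get(g, 1.0) for g in GROUPS},
        "group_sizes": {g: spec.group_sizes.get(g, 0) for g in GROUPS},
        "baseline_log_mean": spec.baseline_log_mean,
        "baseline_log_sd": spec.baseline_log_sd,
        "noise_log_sd": spec.noise_log_sd,
        "seed": spec.seed,
    }
    return mat, labels, ground_truth


def naive_flux_matrix(
    net: KnowledgeNetwork, mat: ExpressionMatrix, missing_floor: float = 0.0
) -> FluxMatrix:
    """Brute-force per-entry flux evaluation, independent of the engine.

    Re-walks the network with plain Python floats for every
    (sample, pathway) entry.  Quadratically slower than
    :func:`pathflux.flux.compute_flux_matrix`; exists as an oracle for
    tests and as the producer of the fixture bundle's expected fluxes.
    """
    def conc(species_id: str, expr: dict[str, float]) -> float:
        if species_id in net.species:
            sp = net.species[species_id]
            if sp.is_constant:
                return float(sp.constant_value)
            c = 1.0
            for g in sorted(sp.constituents):
                c *= expr.get(g, missing_floor)
            return c
        return expr.get(species_id, missing_floor)

    def rflux(rid: str, expr: dict[str, float]) -> float:
        rxn = net.reactions[rid]
        f = rxn.rate_constant
        for p in rxn.participants:
            if p.role in ACTIVATING_ROLES:
                f *= conc(p.species_id, expr)
            else:
                f /= 1.0 + conc(p.species_id, expr)
        return f

    def base(pid: str, expr: dict[str, float]) -> float:
        rids = sorted(net.pathways[pid].reaction_ids)
        return sum(rflux(r, expr) for r in rids) / len(rids)

    values = np.zeros((len(mat.sample_ids), len(net.pathways)))
    for si, sid in enumerate(mat.sample_ids):
        expr = mat.data[sid].astype(float).to_dict()
        for pi, (pid, pw) in enumerate(net.pathways.items()):
            f = base(pid, expr)
            if pw.crosstalk_ids:
                cids = sorted(pw.crosstalk_ids)
                f -= sum(base(q, expr) for q in cids) / len(cids)
            values[si, pi] = f
    df = pd.DataFrame(values, index=mat.sample_ids, columns=list(net.pathways))
    return FluxMatrix(df, {pid: pw.klass for pid, pw in net.pathways.items()})


def write_fixture_bundle(
    out_dir: str | Path,
    network_spec: NetworkSpec | None = None,
    cohort_spec: CohortSpec | None = None,
) -> dict[str, Path]:
    """Write a small canonical bundle for tests and documentation.

    Contents: ``network.json``, ``expression.tsv``, ``labels.tsv``,
    ``expected_flux.tsv`` + ``pathway_klass.tsv`` (computed by the
    brute-force evaluator, not the production engine) and
    ``ground_truth.json``.  Byte-identical when regenerated with the
    same specs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nspec = network_spec or NetworkSpec(
        n_genes=12, n_pathways=3, reactions_per_pathway=3, seed=7
    )
    cspec = cohort_spec or CohortSpec(
        group_sizes={"malignant": 6, "benign": 6, "control": 6}, seed=7
    )
    net = generate_network(nspec)
    mat, labels, truth = generate_cohort(net, cspec)
    paths = {
        "network": out / "network.json",
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "expected_flux": out / "expected_flux.tsv",
        "pathway_klass": out / "pathway_klass.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_network(net, paths["network"])
    mat.to_tsv(paths["expression"])
    write_labels_tsv(labels, paths["labels"])
    naive_flux_matrix(net, mat).to_tsv(
        paths["expected_flux"], paths["pathway_klass"]
    )
    paths["ground_truth"].write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
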