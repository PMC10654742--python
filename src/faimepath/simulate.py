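"""Synthetic whole-blood RNA-seq cohort with known pathway-level truth.

The generator emulates the design of a preclinical systemic sclerosis
study: healthy controls sampled once at baseline, patients sampled at
baseline and follow-up, with the patient group split into subjects that
remain stable and subjects that progress to definite disease.  Counts
are negative binomial with log-normal library-size factors; a baseline
group effect shifts the genes of a known subset of pathways in all
patient samples, and a progression effect shifts the genes of a second
subset only in the follow-up samples of evolving subjects.  Both
effects alternate in direction across pathways (some pathways rise,
others fall).  For the baseline effect the signs are additionally
balanced by gene count: single-sample pathway scores are competitive
(rank-based within a sample), so a one-signed shift of many genes
would displace the ranks of every unaffected gene and smear the group
effect across null pathways; sign balance keeps the pathway-level
ground truth recoverable.  Stable subjects' follow-up samples are
fresh draws from their baseline distribution: biological stability plus
sampling noise.

Ground truth must be unambiguous at the pathway level, so the genes of
effect-carrying pathways are drawn from reserved, mutually disjoint
blocks of the gene universe and never appear in null pathways; null
pathways may overlap one another freely.  The truth record names the
affected and progression pathways (with the progression sign per
pathway) so downstream sensitivity and false-discovery proportions can
be scored exactly.

All randomness flows from a single seed through numpy's Generator
(PCG64), so identical specs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Cohort sizes default to the study design being emulated: 16 healthy
    controls, 33 patients (19 stable / 14 evolving) with paired
    baseline and follow-up samples.
    """

    n_genes: int = 4000
    n_hc: int = 16
    n_stable: int = 19
    n_evolving: int = 14
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (8, 60)
    n_affected_pathways: int = 20
    delta_baseline: float = 1.0  # log2 shift in patient samples
    n_progression_pathways: int = 15
    delta_progression: float = 1.0  # extra log2 shift at follow-up, evolving only
    nb_dispersion: float = 0.2
    libsize_meanlog: float = 0.0
    libsize_sdlog: float = 0.3
    base_log2_mean: float = 5.0
    base_log2_sd: float = 2.0
    n_root_categories: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if lo < 5:
            raise ValueError("pathway sizes must be >= 5")
        if lo > hi:
            raise ValueError("invalid pathway size range")
        for name in (
            "n_genes", "n_hc", "n_stable", "n_evolving", "n_pathways",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_affected_pathways + self.n_progression_pathways > self.n_pathways:
            raise ValueError("more effect pathways than pathways")
        if hi > self.n_genes:
            raise ValueError("largest pathway exceeds the gene universe")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_stable + self.n_evolving


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def generate_gene_sets(spec: SyntheticSpec) -> GeneSetCollection:
    """Pathway collection over a synthetic gene universe.

    The first ``n_affected_pathways`` pathway ids carry the baseline
    group effect and the next ``n_progression_pathways`` the progression
    effect; their member genes come from disjoint reserved blocks.  The
    remaining (null) pathways sample from the rest of the universe.  A
    single-level hierarchy assigns every pathway to one of
    ``n_root_categories`` root categories, all of which are used.
    """
    rng = _rng(spec, 0)
    genes = np.array([f"G{i + 1:05d}" for i in range(spec.n_genes)])
    lo, hi = spec.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)

    n_effect = spec.n_affected_pathways + spec.n_progression_pathways
    effect_total = int(sizes[:n_effect].sum())
    if effect_total + hi > spec.n_genes:
        raise ValueError(
            "gene universe too small for disjoint effect pathways plus "
            f"null pathways (need > {effect_total + hi}, have {spec.n_genes})"
        )
    perm = rng.permutation(spec.n_genes)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    cursor = 0
    for i in range(spec.n_pathways):
        pid = f"P{i + 1:04d}"
        size = int(sizes[i])
        if i < n_effect:
            idx = perm[cursor : cursor + size]
            cursor += size
        else:
            pool = perm[effect_total:]
            idx = rng.choice(pool, size=size, replace=False)
        sets[pid] = (f"Synthetic pathway {i + 1}", tuple(genes[np.sort(idx)]))

    r = spec.n_root_categories
    if spec.n_pathways < r:
        raise ValueError("fewer pathways than root categories")
    root_ids = [f"ROOT{j + 1:02d}" for j in range(r)]
    assign = np.concatenate(
        [np.arange(r), rng.integers(0, r, size=spec.n_pathways - r)]
    )
    rng.shuffle(assign)
    hierarchy = {
        f"P{i + 1:04d}": root_ids[int(assign[i])] for i in range(spec.n_pathways)
    }
    return GeneSetCollection(sets=sets, hierarchy=hierarchy)


def affected_pathway_ids(spec: SyntheticSpec) -> list[str]:
    return [f"P{i + 1:04d}" for i in range(spec.n_affected_pathways)]


def progression_pathway_ids(spec: SyntheticSpec) -> list[str]:
    start = spec.n_affected_pathways
    return [
        f"P{i + 1:04d}"
        for i in range(start, start + spec.n_progression_pathways)
    ]


def generate_cohort(
    spec: SyntheticSpec, sets: GeneSetCollection
) -> tuple[CountMatrix, dict]:
    """Draw counts and metadata for the full paired cohort.

    Counts are NB(mean = 2^(b_g + delta_gs) * L_s, dispersion alpha)
    with gene base log2-means b_g ~ Normal and library factors L_s
    log-normal; dispersion 0 degenerates to Poisson.  Returns the
    validated count matrix and a truth record listing the affected
    pathways, the progression pathways with their shift signs, and the
    seed.
    """
    rng = _rng(spec, 1)
    gene_index = {g: i for i, g in enumerate(
        [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    )}

    # sample frame
    records = []
    for i in range(spec.n_hc):
        records.append((f"HC{i + 1:02d}", f"HC{i + 1:02d}", "HC", "none", "baseline"))
    for i in range(spec.n_subjects):
        outcome = "stable" if i < spec.n_stable else "evolving"
        sid = f"S{i + 1:02d}"
        records.append((f"{sid}_T0", sid, "PreSSc", outcome, "baseline"))
        records.append((f"{sid}_T1", sid, "PreSSc", outcome, "followup"))
    md = pd.DataFrame(
        records,
        columns=["sample_id", "subject_id", "group", "outcome", "timepoint"],
    ).set_index("sample_id")

    # per-subject covariates (age roughly matching the emulated cohort)
    subjects = md["subject_id"].unique()
    age = {s: float(np.round(rng.normal(56.0, 12.0), 1)) for s in subjects}
    sex = {s: ("F" if rng.random() < 0.85 else "M") for s in subjects}
    md["age"] = md["subject_id"].map(age)
    md["sex"] = md["subject_id"].map(sex)

    n_samples = len(md)
    b = rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=spec.n_genes)
    lib = rng.lognormal(spec.libsize_meanlog, spec.libsize_sdlog, size=n_samples)

    delta = np.zeros((spec.n_genes, n_samples))
    affected = affected_pathway_ids(spec)
    progression = progression_pathway_ids(spec)
    # baseline effect signs: greedy gene-count balance so up- and
    # down-shifted gene totals stay close (see module docstring)
    sizes = {pid: len(sets.genes_of(pid)) for pid in affected}
    asigns: dict[str, int] = {}
    n_up = n_down = 0
    for pid in sorted(affected, key=lambda p: -sizes[p]):
        if n_up <= n_down:
            asigns[pid] = 1
            n_up += sizes[pid]
        else:
            asigns[pid] = -1
            n_down += sizes[pid]
    asigns = {pid: asigns[pid] for pid in affected}
    presssc_cols = np.flatnonzero((md["group"] == "PreSSc").to_numpy())
    if spec.delta_baseline != 0.0:
        for pid in affected:
            rows = [gene_index[g] for g in sets.genes_of(pid)]
            delta[np.ix_(rows, presssc_cols)] += asigns[pid] * spec.delta_baseline
    signs = {pid: (1 if j % 2 == 0 else -1) for j, pid in enumerate(progression)}
    evolving_fup = (
        (md["outcome"] == "evolving") & (md["timepoint"] == "followup")
    ).to_numpy()
    if progression and spec.delta_progression != 0.0:
        cols = np.flatnonzero(evolving_fup)
        for pid in progression:
            rows = [gene_index[g] for g in sets.genes_of(pid)]
            delta[np.ix_(rows, cols)] += signs[pid] * spec.delta_progression

    mu = np.exp2(b[:, None] + delta) * lib[None, :]
    if spec.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / spec.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(
        counts=pd.DataFrame(
            counts.astype(np.int64),
            index=list(gene_index),
            columns=md.index,
        ),
        metadata=md,
    )
    truth = {
        "affected_pathways": asigns,
        "progression_pathways": signs,
        "spec": asdict(spec),
    }
    return cm, truth
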