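"""Synthetic multi-omic cohort generator with a known truth ledger.

Emulates a postmortem-brain study: three diagnosis groups (CON / MDD / PTSD)
sampled in two cortical regions (DLPFC, sgPFC), profiled at the protein
(DIA log10 intensity), transcript (RNA-seq counts) and miRNA (small-RNA
counts) levels on the same donors.

The planted structure mirrors the biology the pipeline is built to detect:

* signed co-expression modules among proteins, each driven by a latent
  eigengene; a subset of module eigengenes carries a diagnosis effect
  (disease-associated modules);
* matched transcripts of module proteins share the same eigengene (diluted),
  so RNA and protein changes are concordant where transcription drives both;
* a few regulator miRNAs are upregulated in cases and repress their target
  proteins post-transcriptionally: the coupling enters the protein equation
  only, never the transcript counts, so targeted proteins fall while their
  mRNAs stay flat — the signature of miRNA-mediated translational repression;
* additional singleton differential features per modality.

Protein values follow

    x_ij = mu_i + lambda_i * e_{m(i),j} - sum_r gamma_ir * z_rj + eps_ij

with eigengene e_mj = alpha_m(dx_j) + N(0,1), z_rj the centered log2-FPKM of
regulator r in sample j, and eps ~ N(0, 1 - lambda_i^2) so module members
have unit variance before miRNA coupling.  Counts are negative binomial with
per-feature dispersion drawn from a log-normal and per-sample library-size
factors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, GeneSetCollection, SampleTable, ValidationError

CELL_TYPES = ("neuron", "astrocyte", "microglia", "oligodendrocyte", "endothelial")


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for the generator; defaults are the reference cohort."""

    n_per_group: int = 19
    regions: tuple[str, ...] = ("DLPFC", "sgPFC")
    n_proteins: int = 2600
    n_genes: int = 8000
    n_mirnas: int = 1365
    n_modules: int = 8
    module_size_min: int = 20
    module_size_max: int = 80
    loading_min: float = 0.4
    loading_max: float = 0.9
    dx_effect: float = 0.8            # eigengene shift in cases, SD units
    n_regulator_mirnas: int = 3
    targets_per_regulator: int = 12
    gamma: float = 0.5                # log10-intensity units per log2-FPKM unit
    gamma_rel_spread: float = 0.75    # per-target gamma ~ gamma * U(1-s, 1+s)
    module_repression_frac: float = 0.3   # diffuse repression strength, x gamma
    module_repressed_frac: float = 0.3    # fraction of non-target members hit
    module_loading_halfwidth: float = 0.1   # per-module loading band half-width
    mirna_log2fc: float = 1.5         # planted regulator upregulation in cases
    transcript_compensation: float = 0.4  # buffering: centered gamma-coupling on transcripts
    noise_sd: float = 0.5             # protein residual SD, log10 units
    rna_eigengene_coupling: float = 0.1   # ln-mean units per eigengene SD
    n_de_proteins: int = 60           # protein-only differential features
    de_protein_log2fc: float = 1.0
    n_de_genes: int = 150             # transcript-only differential features
    de_gene_log2fc: float = 1.0
    n_de_shared: int = 40             # transcription-driven DE: both levels shift
    de_shared_attenuation: float = 0.8  # protein effect as a fraction of the RNA effect
    dispersion_log_mean: float = -2.0
    dispersion_log_sd: float = 0.5
    libsize_min: float = 0.5
    libsize_max: float = 2.0
    protein_missing_frac: float = 0.0

    def validate(self) -> None:
        if self.module_size_max * self.n_modules > self.n_proteins:
            raise ValidationError("planted module sizes may exceed n_proteins")
        if self.module_size_min > self.module_size_max:
            raise ValidationError("empty module size range")
        if self.targets_per_regulator > self.module_size_min:
            raise ValidationError("targets_per_regulator exceeds minimum module size")
        if self.n_regulator_mirnas > max(self.n_modules, 1) or self.n_regulator_mirnas > self.n_mirnas:
            raise ValidationError("too many regulator miRNAs for the configured cohort")


@dataclasses.dataclass
class TruthLedger:
    """Ground truth of every planted effect, serializable for audit."""

    seed: int
    protein_modules: dict[str, str]          # protein id -> module name ("" = background)
    gene_modules: dict[str, str]             # matched gene id -> module name
    module_alpha_ptsd: dict[str, float]      # eigengene dx shift per module
    module_alpha_mdd: dict[str, float]
    loadings: dict[str, float]               # protein id -> lambda
    de_proteins: dict[str, float]            # planted singleton log2FC (both case groups)
    de_genes: dict[str, float]
    de_mirnas: dict[str, float]              # regulator id -> log2FC in cases
    regulators: list[dict]                   # {mirna_id, module, targets: {protein_id: gamma}}
    mirna_lengths: dict[str, int]
    module_celltype: dict[str, str]
    id_map: dict[str, str]                   # gene id -> matched protein id

    def module_members(self, module: str) -> list[str]:
        return [p for p, m in self.protein_modules.items() if m == module]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative binomial draws, NB2 parameterization (var = mu + alpha mu^2)."""
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(np.broadcast_to(size, mean.shape), p).astype(float)


def _sample_table(cfg: CohortConfig, rng: np.random.Generator) -> SampleTable:
    n_donors = 3 * cfg.n_per_group
    dx = np.repeat(["CON", "MDD", "PTSD"], cfg.n_per_group)
    donor_ids = [f"D{i + 1:03d}" for i in range(n_donors)]
    age = np.clip(rng.normal(50, 12, n_donors), 20, 90).round(1)
    sex = rng.choice(["M", "F"], n_donors)
    ancestry = rng.choice(["EUR", "AFR"], n_donors, p=[0.7, 0.3])
    pmi = np.clip(rng.normal(20, 6, n_donors), 2, 60).round(1)
    rows = []
    for region in cfg.regions:
        rin = np.clip(rng.normal(7.5, 0.8, n_donors), 4, 10).round(2)
        for i, donor in enumerate(donor_ids):
            rows.append(
                dict(sample_id=f"{donor}_{region}", donor_id=donor, dx=dx[i],
                     region=region, sex=sex[i], age=age[i], ancestry=ancestry[i],
                     pmi=pmi[i], rin=rin[i])
            )
    return SampleTable(pd.DataFrame(rows))


def generate_cohort(
    cfg: CohortConfig, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, SampleTable, TruthLedger]:
    """Generate (protein, rna, mirna, samples, truth) for one cohort.

    Deterministic given (cfg, seed).  Matched gene/protein identifiers share a
    numeric stem (GENE00042 <-> PROT00042) for the first ``n_proteins`` genes.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    samples = _sample_table(cfg, rng)
    sdf = samples.frame
    n = len(sdf)
    is_ptsd = (sdf["dx"] == "PTSD").to_numpy(float)
    is_mdd = (sdf["dx"] == "MDD").to_numpy(float)
    is_case = is_ptsd + is_mdd

    protein_ids = [f"PROT{i + 1:05d}" for i in range(cfg.n_proteins)]
    gene_ids = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
    mirna_ids = [f"hsa-mir-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    id_map = {gene_ids[i]: protein_ids[i] for i in range(min(cfg.n_proteins, cfg.n_genes))}

    # -- module scaffold ---------------------------------------------------
    module_names = [f"M{k + 1}" for k in range(cfg.n_modules)]
    sizes = rng.integers(cfg.module_size_min, cfg.module_size_max + 1, cfg.n_modules)
    assignment: dict[str, str] = {p: "" for p in protein_ids}
    pos = 0
    for name, size in zip(module_names, sizes):
        for p in protein_ids[pos:pos + size]:
            assignment[p] = name
        pos += size

    # disease-associated eigengenes: the regulator-targeted modules are down
    # in both disorders (repressed by upregulated miRNAs); when there are no
    # regulators the first module carries the dx effect
    alpha_ptsd = {m: 0.0 for m in module_names}
    alpha_mdd = {m: 0.0 for m in module_names}
    n_reg = cfg.n_regulator_mirnas
    for k in range(min(max(n_reg, 1), cfg.n_modules)):
        alpha_ptsd[module_names[k]] = -cfg.dx_effect
        alpha_mdd[module_names[k]] = -cfg.dx_effect

    eig = {}
    for m in module_names:
        eig[m] = alpha_ptsd[m] * is_ptsd + alpha_mdd[m] * is_mdd + rng.normal(0, 1, n)

    # loadings: each module draws a narrow band inside the configured range,
    # so within-module loading spread stays small (as in real co-expression
    # modules, where members track their eigengene comparably)
    w = min(cfg.module_loading_halfwidth,
            (cfg.loading_max - cfg.loading_min) / 2.0)
    centers = {m: float(rng.uniform(cfg.loading_min + w, cfg.loading_max - w))
               for m in module_names}
    loadings = {p: 0.0 for p in protein_ids}
    for p in protein_ids:
        if assignment[p]:
            c = centers[assignment[p]]
            loadings[p] = float(rng.uniform(c - w, c + w))

    # -- miRNA counts ------------------------------------------------------
    mirna_len = {mid: int(rng.integers(60, 121)) for mid in mirna_ids}
    mirna_base = rng.uniform(np.log(0.2), np.log(2000), cfg.n_mirnas)
    mirna_base[:n_reg] = rng.uniform(np.log(300), np.log(2000), n_reg)  # regulators well expressed
    mirna_disp = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, cfg.n_mirnas))
    libsize_mirna = rng.uniform(cfg.libsize_min, cfg.libsize_max, n)
    log_mu = np.tile(mirna_base[:, None], (1, n))
    delta_ln = cfg.mirna_log2fc * np.log(2.0)
    for r in range(n_reg):
        log_mu[r] += delta_ln * is_case
    mirna_counts = _nb_sample(rng, np.exp(log_mu) * libsize_mirna[None, :], mirna_disp[:, None])
    mirna = ExpressionMatrix(mirna_ids, samples.sample_ids, mirna_counts, "mirna_counts")

    # regulator repression signal: centered log2(FPKM+1) of each regulator
    totals = mirna_counts.sum(axis=0)
    z = np.empty((n_reg, n))
    for r in range(n_reg):
        fpkm = mirna_counts[r] * 1e9 / (mirna_len[mirna_ids[r]] * totals)
        lz = np.log2(fpkm + 1.0)
        z[r] = lz - lz.mean()

    regulators: list[dict] = []
    de_mirnas = {mirna_ids[r]: cfg.mirna_log2fc for r in range(n_reg)}
    coupling = np.zeros((cfg.n_proteins, n))
    # transcriptional buffering: targets repressed more than the regulator's
    # average get a compensatory transcript term (and vice versa), centered so
    # the net transcript change across targets is zero
    rna_buffer = np.zeros((cfg.n_genes, n))
    pidx = {p: i for i, p in enumerate(protein_ids)}
    n_matched = min(cfg.n_proteins, cfg.n_genes)
    for r in range(n_reg):
        module = module_names[r % cfg.n_modules] if cfg.n_modules else ""
        members = [p for p in protein_ids if assignment[p] == module]
        targets = list(rng.choice(members, size=min(cfg.targets_per_regulator, len(members)), replace=False))
        lo, hi = 1.0 - cfg.gamma_rel_spread, 1.0 + cfg.gamma_rel_spread
        gam = cfg.gamma * rng.uniform(lo, hi, len(targets))
        gammas = {t: float(g) for t, g in zip(targets, gam)}
        gbar = gam.mean() if len(gam) else 0.0
        for t, g in gammas.items():
            coupling[pidx[t]] -= g * z[r]
            if pidx[t] < n_matched:
                rna_buffer[pidx[t]] += (
                    cfg.transcript_compensation * np.log(10.0) * (g - gbar) * z[r]
                )
        # diffuse network-level repression: the regulator also weakly represses
        # a fraction of its module beyond the direct targets (protein only),
        # as network-level miRNA regulators do
        g_diff = float(cfg.module_repression_frac * cfg.gamma)
        others = [p for p in members if p not in gammas]
        n_diff = int(round(cfg.module_repressed_frac * len(others)))
        if g_diff > 0 and n_diff > 0:
            for p in rng.choice(others, size=n_diff, replace=False):
                coupling[pidx[p]] -= g_diff * z[r]
        regulators.append({"mirna_id": mirna_ids[r], "module": module,
                           "targets": gammas, "module_gamma": g_diff})

    # -- protein matrix ----------------------------------------------------
    mu = rng.normal(7.0, 0.5, cfg.n_proteins)
    lam = np.array([loadings[p] for p in protein_ids])
    prot = mu[:, None] + coupling + rng.normal(0, cfg.noise_sd, (cfg.n_proteins, n))
    for p, m in assignment.items():
        if m:
            prot[pidx[p]] += loadings[p] * eig[m]

    # singleton DE proteins drawn from the background, shifted in both case
    # groups; a further n_de_shared background pairs are transcription-driven
    # (gene and protein shift together, protein attenuated), planted on the
    # RNA side below
    background = [p for p in protein_ids if not assignment[p]]
    reserved = {t for reg in regulators for t in reg["targets"]}
    de_pool = [p for p in background if p not in reserved]
    n_single = min(cfg.n_de_proteins, len(de_pool))
    picked = list(rng.choice(de_pool, size=n_single + min(
        cfg.n_de_shared, max(len(de_pool) - n_single, 0)), replace=False))
    de_prot_ids = picked[:n_single]
    shared_prot_ids = [p for p in picked[n_single:] if pidx[p] < n_matched]
    de_proteins = {}
    for p in de_prot_ids:
        lfc = float(cfg.de_protein_log2fc * rng.choice([-1.0, 1.0]))
        de_proteins[p] = lfc
        prot[pidx[p]] += lfc * np.log10(2.0) * is_case
    shared_gene_lfc: dict[str, float] = {}
    for p in shared_prot_ids:
        g_lfc = float(cfg.de_gene_log2fc * rng.choice([-1.0, 1.0]))
        p_lfc = cfg.de_shared_attenuation * g_lfc
        shared_gene_lfc[gene_ids[pidx[p]]] = g_lfc
        de_proteins[p] = p_lfc
        prot[pidx[p]] += p_lfc * np.log10(2.0) * is_case

    if cfg.protein_missing_frac > 0:
        # missing-not-at-random: the lowest-intensity cells go missing first
        q = np.quantile(prot, cfg.protein_missing_frac)
        drop = (prot < q) & (rng.uniform(size=prot.shape) < 0.8)
        prot = np.where(drop, np.nan, prot)
    protein = ExpressionMatrix(protein_ids, samples.sample_ids, prot, "protein_log_intensity")

    # -- RNA counts --------------------------------------------------------
    gene_base = rng.uniform(np.log(0.2), np.log(1000), cfg.n_genes)
    gene_disp = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, cfg.n_genes))
    libsize_rna = rng.uniform(cfg.libsize_min, cfg.libsize_max, n)
    log_mu_rna = np.tile(gene_base[:, None], (1, n))
    gene_modules: dict[str, str] = {}
    for i in range(n_matched):
        m = assignment[protein_ids[i]]
        if m:
            gene_modules[gene_ids[i]] = m
            # matched transcripts of module proteins are reliably quantifiable
            log_mu_rna[i] = np.maximum(log_mu_rna[i], np.log(3.0))
            log_mu_rna[i] += cfg.rna_eigengene_coupling * lam[i] * eig[m]
    # no direct miRNA repression on transcripts (post-transcriptional); only
    # the zero-centered buffering term computed above
    log_mu_rna += rna_buffer
    de_gene_pool = [g for g in gene_ids[n_matched:]]
    de_gene_ids = list(rng.choice(de_gene_pool, size=min(cfg.n_de_genes, len(de_gene_pool)), replace=False))
    de_genes = {}
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for g in de_gene_ids:
        lfc = float(cfg.de_gene_log2fc * rng.choice([-1.0, 1.0]))
        de_genes[g] = lfc
        log_mu_rna[gidx[g]] += lfc * np.log(2.0) * is_case
    for g, lfc in shared_gene_lfc.items():
        de_genes[g] = lfc
        # shared features must be quantifiable at the transcript level too
        log_mu_rna[gidx[g]] = np.maximum(log_mu_rna[gidx[g]], np.log(5.0))
        log_mu_rna[gidx[g]] += lfc * np.log(2.0) * is_case
    rna_counts = _nb_sample(rng, np.exp(log_mu_rna) * libsize_rna[None, :], gene_disp[:, None])
    rna = ExpressionMatrix(gene_ids, samples.sample_ids, rna_counts, "rna_counts")

    module_celltype = {m: CELL_TYPES[k % len(CELL_TYPES)] for k, m in enumerate(module_names)}
    truth = TruthLedger(
        seed=seed,
        protein_modules=assignment,
        gene_modules=gene_modules,
        module_alpha_ptsd=alpha_ptsd,
        module_alpha_mdd=alpha_mdd,
        loadings=loadings,
        de_proteins=de_proteins,
        de_genes=de_genes,
        de_mirnas=de_mirnas,
        regulators=regulators,
        mirna_lengths=mirna_len,
        module_celltype=module_celltype,
        id_map=id_map,
    )
    return protein, rna, mirna, samples, truth


def generate_celltype_reference(
    n_types: int = 5,
    markers_per_type: int = 50,
    seed: int = 0,
    n_genes: int = 2000,
    gene_ids: list[str] | None = None,
    marker_genes: dict[str, list[str]] | None = None,
    marker_fold: float = 10.0,
) -> tuple[ExpressionMatrix, GeneSetCollection]:
    """Cell-type mean expression reference (log scale) plus marker gene sets.

    Marker genes are >= ``marker_fold``-fold higher (linear scale) in their own
    type than in every other; background genes are flat up to noise.  Pass
    ``marker_genes`` (type -> gene list) to pin specific genes as markers, e.g.
    the members of a planted module.
    """
    if n_types < 2:
        raise ValidationError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    types = list(CELL_TYPES[:n_types]) + [f"type{i}" for i in range(len(CELL_TYPES), n_types)]
    if gene_ids is None:
        gene_ids = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    if marker_genes is None:
        if markers_per_type * n_types > len(gene_ids):
            raise ValidationError("markers_per_type x n_types exceeds gene count")
        marker_genes = {}
        pool = list(rng.permutation(gene_ids))
        for k, t in enumerate(types):
            marker_genes[t] = pool[k * markers_per_type:(k + 1) * markers_per_type]
    base = rng.normal(3.0, 0.5, len(gene_ids))  # log10 mean per gene
    means = np.tile(base[:, None], (1, n_types)) + rng.normal(0, 0.05, (len(gene_ids), n_types))
    gi = {g: i for i, g in enumerate(gene_ids)}
    lift = np.log10(marker_fold) + 0.3  # headroom over the noise
    for k, t in enumerate(types):
        for g in marker_genes.get(t, []):
            means[gi[g], :] = base[gi[g]]
            means[gi[g], k] = base[gi[g]] + lift
    ref = ExpressionMatrix(gene_ids, types, means, "protein_log_intensity")
    markers = GeneSetCollection({t: list(gs) for t, gs in marker_genes.items() if gs},
                                {t: "synthetic marker set" for t in marker_genes})
    return ref, markers


def generate_trait_gene_lists(
    truth: TruthLedger,
    trait_specs: list[tuple[str, str, float]],
    seed: int,
    universe: list[str] | None = None,
    list_length: int = 200,
) -> dict[str, list[str]]:
    """Ranked trait gene lists with planted module enrichment.

    For each (trait, module, odds) the realized overlap k with the module is
    drawn Binomial(L, k*/L) where k* solves the 2x2 odds-ratio equation so the
    requested odds holds in expectation; odds=1 reduces to the hypergeometric
    expectation L*m/U.  Gene identifiers are the matched-gene side of the
    truth id_map.
    """
    rng = np.random.default_rng(seed)
    prot2gene = {p: g for g, p in truth.id_map.items()}
    if universe is None:
        universe = sorted(truth.id_map)
    uni = list(universe)
    U = len(uni)
    L = min(list_length, U)
    out: dict[str, list[str]] = {}
    for trait, module, odds in trait_specs:
        members = [prot2gene[p] for p in truth.module_members(module) if p in prot2gene]
        members = [g for g in members if g in set(uni)]
        m = len(members)
        if m == 0:
            raise ValidationError(f"module {module!r} has no genes in the universe")
        # solve (1-w)k^2 + (U-L-m+w(L+m))k - L*m*w = 0 for k in [0, min(L, m)]
        w = float(odds)
        if abs(w - 1.0) < 1e-12:
            k_star = L * m / U
        else:
            a, b, c = (1.0 - w), (U - L - m + w * (L + m)), -L * m * w
            disc = b * b - 4 * a * c
            k_star = (-b + np.sqrt(disc)) / (2 * a)
            if not (0 <= k_star <= min(L, m) + 1e-9):
                k_star = (-b - np.sqrt(disc)) / (2 * a)
        if k_star > m + 1e-9:
            raise ValidationError(f"requested odds {odds} needs overlap {k_star:.1f} > module size {m}")
        k = int(rng.binomial(L, min(1.0, k_star / L)))
        k = min(k, m, L)
        outside_pool = [g for g in uni if g not in set(members)]
        k = max(k, L - len(outside_pool))  # small universes: list must fill up
        inside = list(rng.choice(members, size=k, replace=False))
        outside = list(rng.choice(outside_pool, size=L - k, replace=False))
        ranked = inside + outside
        rng.shuffle(ranked)
        out[trait] = ranked
    return out
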