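"""Seeded synthetic multi-omics cohorts with planted ground truth.

The generator emulates the statistical structure of a two-population,
two-generation heat-stress experiment: per-sample TE caller outputs
(reference genotyping statuses plus two independent non-reference
insertion callers), a gene annotation, and per-gene differential tables
for two assays (RNA, ATAC) x two populations x three contrasts.  Every
planted quantity — gene effect classes, true log2 fold-changes, TE
intervals and population membership, control-drift and transgenerational
flags — is recorded in a :class:`TruthManifest` so that each pipeline
stage can be scored against ground truth.

Planted structure, briefly:

* a fraction of genes respond to treatment in both populations (shared)
  or in exactly one (unique); true RNA/ATAC effects share a sign and are
  correlated (``concordance_rho``);
* genes hosting a non-reference TE in population 1 are pushed toward
  down-regulation with odds ``te_assoc_odds`` (a planted TE-direction
  association; odds 1 plants none);
* a fraction of each population's responders keep a descendant-generation
  response, ``g6 = transgen_rho * g3 + noise``;
* control-drift genes acquire a spurious generation effect that shows up
  in both the control-vs-control contrast and the descendant contrast;
* caller outputs drop calls with probability ``1 - detection_prob`` and
  jitter coordinates with rounded normal noise.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .te_consensus import NON_REFERENCE, REFERENCE

TE_FAMILIES = [
    "roo", "jockey", "copia", "412", "blood", "doc", "I-element",
    "F-element", "297", "gypsy", "BS", "hobo",
]
CALLERS = ("popte2", "temp2")
CONTRASTS = ("G3_treat", "G6_ancestral", "CtrlDrift")
ASSAYS = ("RNA", "ATAC")

# free-text description vocabulary; some phrases carry the keyword-search
# targets (stress / epigenome groups), the rest are neutral fillers
_DESC_STRESS = [
    "heat stress response factor", "oxidative stress induced protein",
    "stress-activated kinase",
]
_DESC_EPI = [
    "histone methyltransferase", "chromatin remodeling factor",
    "epigenetic silencing component", "histone deacetylase complex subunit",
]
_DESC_NEUTRAL = [
    "hypothetical protein", "predicted membrane transporter",
    "cytoskeletal adaptor", "ribosomal assembly factor",
    "cuticle structural constituent",
]


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults define the simulated study.

    Sizes are scaled down from a fly-genome experiment (thousands of genes,
    hundreds of insertions) to keep simulations desk-fast while leaving
    every class well populated.  Effect sizes are in log2 units.
    """

    n_genes: int = 2000
    n_chroms: int = 4
    chrom_length: int = 6_000_000
    n_samples_per_pop: int = 3
    n_ref_tes: int = 500
    n_nonref_tes: int = 350
    frac_te_near_gene: float = 0.7
    frac_population_unique: float = 0.3
    detection_prob: float = 0.95
    coord_jitter_sd: float = 3.0
    frac_shared_deg: float = 0.25
    frac_unique_deg: float = 0.10
    lfc_effect_mean: float = 1.5
    lfc_effect_sd: float = 0.75
    lfc_noise_sd: float = 0.25
    concordance_rho: float = 0.7
    te_assoc_odds: float = 3.0
    transgen_frac: float = 0.5
    transgen_rho: float = 0.34
    transgen_noise_sd: float = 0.5
    frac_control_drift: float = 0.05
    seed: int = 0
    populations: tuple[str, str] = ("pop1", "pop2")

    # placement geometry
    gene_len_range: tuple[int, int] = (500, 3000)
    te_len_range: tuple[int, int] = (80, 3000)
    link_window: int = 1000

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("counts and lengths must be positive")
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob must be in (0, 1]")
        if self.frac_shared_deg + 2 * self.frac_unique_deg > 1:
            raise ValueError("effect-class fractions exceed 1")
        if not (0 <= self.frac_population_unique <= 1):
            raise ValueError("frac_population_unique must be in [0, 1]")
        if self.te_assoc_odds <= 0:
            raise ValueError("te_assoc_odds must be positive")
        n_slots = self.n_genes + self.n_ref_tes + self.n_nonref_tes
        slot = (self.n_chroms * self.chrom_length) // n_slots
        need = (self.gene_len_range[1] + self.te_len_range[1]
                + 2 * (self.link_window + 100))
        if slot < need:
            raise ValueError(
                f"infeasible placement: slot length {slot} < required {need}; "
                "increase chrom_length or reduce entity counts"
            )


def easy_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A high-signal, low-noise configuration for recovery checks.

    Strong planted effects, tight observation noise, perfect detection and
    no coordinate jitter: under this regime pipeline output should match
    the truth manifest (near-)exactly.
    """
    base = dict(
        detection_prob=1.0, coord_jitter_sd=0.0,
        lfc_effect_mean=3.0, lfc_effect_sd=0.5, lfc_noise_sd=0.05,
        transgen_rho=0.5, transgen_noise_sd=0.1, seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class TruthManifest:
    """Planted parameters and per-gene / per-TE ground truth."""

    genes: pd.DataFrame       # gene_id, chrom, start, end, strand
    gene_truth: pd.DataFrame  # per-gene classes, true LFCs, flags
    te_truth: pd.DataFrame    # te_id, te_type, interval, family, membership, host gene
    config: SyntheticConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "genes": self.genes.to_dict(orient="list"),
            "gene_truth": self.gene_truth.to_dict(orient="list"),
            "te_truth": self.te_truth.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        for key in ("populations", "gene_len_range", "te_len_range"):
            cfg[key] = tuple(cfg[key])
        return cls(
            genes=pd.DataFrame(payload["genes"]),
            gene_truth=pd.DataFrame(payload["gene_truth"]),
            te_truth=pd.DataFrame(payload["te_truth"]),
            config=SyntheticConfig(**cfg),
        )

    def member_tes(self, population: str) -> pd.DataFrame:
        """Truth TE set present in one population."""
        pops = self.config.populations
        which = "pop1" if population == pops[0] else "pop2"
        mask = self.te_truth["membership"].isin(["both", which])
        return self.te_truth[mask]


def _place_entities(cfg: SyntheticConfig, rng: np.random.Generator):
    """Slot-based placement: genes and intergenic TEs each own one slot.

    Chromosomes are cut into equal slots with >1 kb margins so entities in
    different slots can never fall within the linking window of each other;
    TEs planted near a host gene share that gene's slot.  Deterministic and
    collision-free by construction.
    """
    n_inter = int(round((cfg.n_ref_tes + cfg.n_nonref_tes) * (1 - cfg.frac_te_near_gene)))
    n_slots_total = cfg.n_genes + n_inter
    per_chrom = np.full(cfg.n_chroms, n_slots_total // cfg.n_chroms)
    per_chrom[: n_slots_total % cfg.n_chroms] += 1
    slots = []  # (chrom, slot_start, slot_len)
    for c in range(cfg.n_chroms):
        slot_len = cfg.chrom_length // per_chrom[c]
        for i in range(per_chrom[c]):
            slots.append((f"chr{c + 1}", i * slot_len, slot_len))
    order = rng.permutation(n_slots_total)
    gene_slots = [slots[i] for i in order[: cfg.n_genes]]
    inter_slots = [slots[i] for i in order[cfg.n_genes:]]
    return gene_slots, inter_slots


def generate_truth(config: SyntheticConfig) -> TruthManifest:
    """Draw the full planted cohort state; pure function of the config."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 11]))
    pop1, pop2 = cfg.populations
    margin = cfg.link_window + 100

    gene_slots, inter_slots = _place_entities(cfg, rng)

    # genes: placed in the left part of their slot, leaving room for a
    # near-gene TE to its right without escaping the slot margins
    lengths = rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1,
                           size=cfg.n_genes)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    gene_rows = []
    for i, ((chrom, s0, slen), glen, strand) in enumerate(
        zip(gene_slots, lengths, strands)
    ):
        start = s0 + margin + int(rng.integers(0, 200))
        gene_rows.append({
            "gene_id": f"g{i:05d}", "chrom": chrom,
            "start": start, "end": start + int(glen), "strand": strand,
        })
    genes = pd.DataFrame(gene_rows)

    # TE placement: near-gene TEs sit in their host gene's slot
    n_tes = cfg.n_ref_tes + cfg.n_nonref_tes
    te_types = np.array([REFERENCE] * cfg.n_ref_tes + [NON_REFERENCE] * cfg.n_nonref_tes)
    rng.shuffle(te_types)
    n_near = n_tes - len(inter_slots)
    host_idx = rng.choice(cfg.n_genes, size=n_near, replace=False)
    te_rows = []
    u = cfg.frac_population_unique
    memberships = rng.choice(["both", "pop1", "pop2"], size=n_tes,
                             p=[1 - u, u / 2, u / 2])
    for t in range(n_tes):
        te_len = int(rng.integers(cfg.te_len_range[0], cfg.te_len_range[1] + 1))
        family = str(rng.choice(TE_FAMILIES))
        if t < n_near:
            g = genes.iloc[host_idx[t]]
            relation = str(rng.choice(["upstream_side", "downstream_side", "genic"]))
            if relation == "genic" and te_len < (g["end"] - g["start"]):
                start = int(rng.integers(g["start"], g["end"] - te_len))
            elif relation == "upstream_side" or te_len >= (g["end"] - g["start"]):
                gap = int(rng.integers(1, cfg.link_window))
                start = g["start"] - gap - te_len
            else:
                gap = int(rng.integers(1, cfg.link_window))
                start = g["end"] + gap
            chrom, host = g["chrom"], g["gene_id"]
        else:
            chrom, s0, slen = inter_slots[t - n_near]
            start = s0 + margin
            host = ""
        te_rows.append({
            "te_id": f"te{t:05d}", "te_type": te_types[t], "chrom": chrom,
            "start": int(start), "end": int(start + te_len), "family": family,
            "membership": memberships[t], "host_gene": host,
        })
    te_truth = pd.DataFrame(te_rows)

    # gene effect classes
    n = cfg.n_genes
    n_shared = int(round(cfg.frac_shared_deg * n))
    n_uni = int(round(cfg.frac_unique_deg * n))
    klass = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    klass[perm[:n_shared]] = "shared"
    klass[perm[n_shared:n_shared + n_uni]] = "unique_pop1"
    klass[perm[n_shared + n_uni:n_shared + 2 * n_uni]] = "unique_pop2"

    # genes hosting a non-reference TE, per population
    nr = te_truth[te_truth["te_type"] == NON_REFERENCE]
    nr_host = {
        pop1: set(nr.loc[nr["membership"].isin(["both", "pop1"]), "host_gene"]) - {""},
        pop2: set(nr.loc[nr["membership"].isin(["both", "pop2"]), "host_gene"]) - {""},
    }

    p_down_assoc = cfg.te_assoc_odds / (1.0 + cfg.te_assoc_odds)
    cov = np.array([[1.0, cfg.concordance_rho], [cfg.concordance_rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    truth = {"gene_id": genes["gene_id"].to_numpy()}
    # shared genes respond identically in both populations: one sign and one
    # effect pair drawn per gene, reused where the gene is affected
    base_sign = rng.choice([-1.0, 1.0], size=n)
    z = (rng.standard_normal((n, 2)) @ chol.T) * cfg.lfc_effect_sd
    for pop, uniq in ((pop1, "unique_pop1"), (pop2, "unique_pop2")):
        affected = (klass == "shared") | (klass == uniq)
        sign = base_sign.copy()
        if pop == pop1 and cfg.te_assoc_odds != 1.0:
            # planted direction association: non-reference TE hosts lean down
            hosts = genes["gene_id"].isin(nr_host[pop1]).to_numpy()
            sign[hosts] = np.where(
                rng.random(int(hosts.sum())) < p_down_assoc, -1.0, 1.0
            )
        rna = np.where(affected, sign * (cfg.lfc_effect_mean + z[:, 0]), 0.0)
        atac = np.where(affected, sign * (0.6 * cfg.lfc_effect_mean + z[:, 1]), 0.0)

        transgen = affected & (rng.random(n) < cfg.transgen_frac)
        g6 = np.where(
            transgen,
            cfg.transgen_rho * rna + rng.standard_normal(n) * cfg.transgen_noise_sd,
            0.0,
        )
        drift = rng.random(n) < cfg.frac_control_drift
        drift_lfc = np.where(
            drift,
            rng.choice([-1.0, 1.0], size=n) * (1.0 + np.abs(rng.standard_normal(n))),
            0.0,
        )
        # drift contaminates the descendant contrast; the pipeline must
        # remove it via the control-vs-control lists
        g6_obs_truth = g6 + drift_lfc
        pk = "pop1" if pop == pop1 else "pop2"
        truth[f"class_{pk}"] = np.where(affected, np.where(klass == "shared", "shared", "unique"), "null")
        truth[f"rna_g3_{pk}"] = rna
        truth[f"atac_g3_{pk}"] = atac
        truth[f"rna_g6_{pk}"] = g6_obs_truth
        truth[f"atac_g6_{pk}"] = np.zeros(n)
        truth[f"rna_drift_{pk}"] = drift_lfc
        truth[f"atac_drift_{pk}"] = np.zeros(n)
        truth[f"drift_{pk}"] = drift
        truth[f"transgen_{pk}"] = transgen
        truth[f"tei_{pk}"] = transgen & ~drift

    gene_truth = pd.DataFrame(truth)
    return TruthManifest(genes=genes, gene_truth=gene_truth, te_truth=te_truth,
                         config=cfg)


def truth_te_labels(truth: TruthManifest, population: str) -> pd.DataFrame:
    """Planted per-gene TE-class labels (non-reference takes precedence)."""
    member = truth.member_tes(population)
    hosted = member[member["host_gene"] != ""]
    label = pd.Series("none", index=pd.Index(truth.genes["gene_id"], name="gene_id"))
    ref_hosts = hosted.loc[hosted["te_type"] == REFERENCE, "host_gene"].unique()
    nr_hosts = hosted.loc[hosted["te_type"] == NON_REFERENCE, "host_gene"].unique()
    label.loc[label.index.intersection(ref_hosts)] = REFERENCE
    label.loc[label.index.intersection(nr_hosts)] = NON_REFERENCE
    return label.rename("te_class").reset_index()


def emit_caller_outputs(truth: TruthManifest, config: SyntheticConfig | None = None):
    """Per-sample reference statuses and non-reference caller calls.

    Reference TEs in a population's truth set are genotyped present or
    polymorphic per sample with probability ``detection_prob`` (absent
    otherwise); TEs outside the population are absent everywhere.  Each of
    the two non-reference callers reports a member insertion per sample
    with probability ``detection_prob``, with start/end jittered by rounded
    normal noise.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 23]))
    pops = cfg.populations
    ref = truth.te_truth[truth.te_truth["te_type"] == REFERENCE]
    nonref = truth.te_truth[truth.te_truth["te_type"] == NON_REFERENCE]

    status_tables: dict[str, pd.DataFrame] = {}
    call_tables: dict[str, dict[str, pd.DataFrame]] = {}
    for pi, pop in enumerate(pops):
        member_key = ["both", "pop1" if pi == 0 else "pop2"]
        samples = [f"{pop}_s{i + 1}" for i in range(cfg.n_samples_per_pop)]

        rows = []
        for te in ref.itertuples():
            member = te.membership in member_key
            for s in samples:
                if member and rng.random() < cfg.detection_prob:
                    status = "polymorphic" if rng.random() < 0.3 else "present"
                else:
                    status = "absent"
                rows.append({
                    "te_id": te.te_id, "sample_id": s, "chrom": te.chrom,
                    "start": te.start, "end": te.end, "family": te.family,
                    "status": status,
                })
        status_tables[pop] = pd.DataFrame(rows)

        call_tables[pop] = {}
        members = nonref[nonref["membership"].isin(member_key)]
        for caller in CALLERS:
            crows = []
            for te in members.itertuples():
                for s in samples:
                    if rng.random() >= cfg.detection_prob:
                        continue
                    js = int(round(rng.normal(0, cfg.coord_jitter_sd))) if cfg.coord_jitter_sd else 0
                    je = int(round(rng.normal(0, cfg.coord_jitter_sd))) if cfg.coord_jitter_sd else 0
                    start, end = te.start + js, te.end + je
                    if end <= start:
                        end = start + 1
                    crows.append({
                        "caller": caller, "sample_id": s, "population": pop,
                        "chrom": te.chrom, "start": start, "end": end,
                        "family": te.family,
                    })
            call_tables[pop][caller] = pd.DataFrame(
                crows, columns=["caller", "sample_id", "population",
                                "chrom", "start", "end", "family"],
            )
    return status_tables, call_tables


def emit_diff_tables(
    truth: TruthManifest, config: SyntheticConfig | None = None
) -> dict[tuple[str, str, str], pd.DataFrame]:
    """Observed differential tables for every assay x population x contrast.

    Observed LFC adds per-gene heteroscedastic noise to the true LFC; the
    p-value is the two-sided normal tail of observed/sd, Benjamini-Hochberg
    adjusted within each table (mirroring per-contrast adjustment upstream).
    """
    from statsmodels.stats.multitest import multipletests

    cfg = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 37]))
    n = len(truth.gene_truth)
    out: dict[tuple[str, str, str], pd.DataFrame] = {}
    for pi, pop in enumerate(cfg.populations):
        pk = "pop1" if pi == 0 else "pop2"
        for assay in ASSAYS:
            a = assay.lower()
            for contrast, col in (
                ("G3_treat", f"{a}_g3_{pk}"),
                ("G6_ancestral", f"{a}_g6_{pk}"),
                ("CtrlDrift", f"{a}_drift_{pk}"),
            ):
                true_lfc = truth.gene_truth[col].to_numpy(dtype=float)
                if cfg.lfc_noise_sd == 0:
                    # degenerate zero-noise limit: the observed table is the
                    # truth and significance is exact non-nullness
                    obs = true_lfc
                    p_adj = np.where(true_lfc == 0.0, 1.0, 0.0)
                else:
                    se = cfg.lfc_noise_sd * rng.uniform(0.5, 1.5, size=n)
                    obs = true_lfc + rng.standard_normal(n) * se
                    p = 2.0 * stats.norm.sf(np.abs(obs / se))
                    p_adj = multipletests(p, method="fdr_bh")[1]
                out[(assay, pop, contrast)] = pd.DataFrame({
                    "gene_id": truth.gene_truth["gene_id"],
                    "lfc": obs,
                    "p_adj": p_adj,
                })
    return out


def emit_descriptions(truth: TruthManifest) -> pd.DataFrame:
    """Free-text gene descriptions seeding the keyword search groups."""
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 53]))
    vocab = _DESC_NEUTRAL + _DESC_STRESS + _DESC_EPI
    probs = ([0.16] * len(_DESC_NEUTRAL) + [0.04] * len(_DESC_STRESS)
             + [0.02] * len(_DESC_EPI))
    probs = np.array(probs) / np.sum(probs)
    desc = rng.choice(vocab, size=len(truth.genes), p=probs)
    return pd.DataFrame({"gene_id": truth.genes["gene_id"], "description": desc})


def emit_peak_results(
    truth: TruthManifest, population: str, contrast: str = "G3_treat"
) -> pd.DataFrame:
    """Peak-level ATAC results whose promoter aggregation matches the truth.

    For a random ~80% of genes, one to three peaks overlap the strand-aware
    1 kb promoter; their LFCs scatter around the gene's true ATAC LFC.
    """
    cfg = truth.config
    pk = "pop1" if population == cfg.populations[0] else "pop2"
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 67]))
    col = {"G3_treat": f"atac_g3_{pk}", "G6_ancestral": f"atac_g6_{pk}",
           "CtrlDrift": f"atac_drift_{pk}"}[contrast]
    rows = []
    for g, true_lfc in zip(truth.genes.itertuples(), truth.gene_truth[col]):
        if rng.random() > 0.8:
            continue
        if g.strand == "-":
            p_start, p_end = g.end, g.end + cfg.link_window
        else:
            p_start, p_end = g.start - cfg.link_window, g.start
        for _ in range(int(rng.integers(1, 4))):
            s = int(rng.integers(p_start - 200, p_end - 50))
            w = int(rng.integers(150, 500))
            rows.append({
                "chrom": g.chrom, "start": s, "end": s + w,
                "lfc": float(true_lfc + rng.normal(0, 0.1)),
                "p_adj": float(rng.uniform(0, 1)),
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "lfc", "p_adj"])
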