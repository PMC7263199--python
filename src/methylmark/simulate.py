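"""Synthetic multi-cohort methylation / expression / survival data with planted structure.

The generator emulates the statistical shape of a multi-cancer 450K study:

* per-probe baseline methylation drawn by CpG-island context (island
  promoters low, open sea high), with Beta-distributed measurement noise
  ``Beta(mu * kappa, (1 - mu) * kappa)`` around the probe/sample mean;
* paired tumor / adjacent-normal designs across several cohorts plus an
  unpaired healthy-tissue cohort;
* a planted set of target-cohort-specific hyper-methylated promoter CpGs
  (the "markers"), shifted by ``marker_delta`` in target tumors only;
* a planted set of pan-cancer hyper CpGs shifted in every cohort's tumors
  (decoys that a tissue-specificity cascade must reject);
* a planted high-methylation tumor subcluster (CIMP): a block of
  hypervariable CpGs on which a fraction of target tumors gain an extra
  ``cimp_delta``, with worse survival under a proportional-hazards model;
* negative-binomial expression counts whose log-mean is coupled to
  promoter methylation for the marker genes.

All randomness flows from a single ``numpy`` Generator seeded from the
config, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

CGI_RELATIONS = ["Island", "NShore", "NShelf", "SShore", "SShelf", "OpenSea"]
CGI_PROBS = [0.31, 0.12, 0.05, 0.11, 0.05, 0.36]
FEATURES = ["TSS200", "TSS1500", "5'UTR", "FirstExon", "Body", "3'UTR", "Intergenic"]
FEATURE_PROBS = [0.12, 0.14, 0.12, 0.05, 0.33, 0.04, 0.20]
AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    The defaults describe the canonical study conditions used throughout
    the test-suite: a 50-pair target cohort, four background cancer
    cohorts of 40 tumors / 20 normals, one 30-sample healthy-tissue
    cohort, eight planted markers at a beta shift of 0.4, and a CIMP
    subcluster covering 20% of target tumors.
    """

    seed: int = 0
    n_probes: int = 20000
    cohorts: list = field(default_factory=lambda: [
        ("BRCA", 50, 50),
        ("CANC1", 40, 20),
        ("CANC2", 40, 20),
        ("CANC3", 40, 20),
        ("CANC4", 40, 20),
    ])
    target_cohort: str = "BRCA"
    healthy_cohort: str = "HEALTHY_BREAST"
    n_healthy: int = 30
    n_markers: int = 8
    marker_delta: float = 0.4
    background_hyper_frac: float = 0.02
    background_hyper_delta: float = 0.3
    beta_dispersion: float = 50.0
    cimp_fraction: float = 0.2
    cimp_delta: float = 0.3
    n_cimp_extra: int = 100
    cimp_block_spread: float = 0.6
    survival_hr: float = 3.0
    censor_rate: float = 0.3
    baseline_median_days: float = 1500.0
    expr_coupling: float = -2.0
    n_genes: int = 300
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    nb_size: float = 10.0
    snp_frac: float = 0.05
    sex_frac: float = 0.03

    def validate(self) -> None:
        for name in ("background_hyper_frac", "cimp_fraction", "censor_rate",
                     "snp_frac", "sex_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.n_markers > self.n_probes:
            raise ValueError("n_markers exceeds n_probes")
        ids = [c[0] for c in self.cohorts]
        if self.target_cohort not in ids:
            raise ValueError(f"target_cohort {self.target_cohort!r} not among cohorts {ids}")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cohort ids")
        if self.survival_hr <= 0:
            raise ValueError("survival_hr must be > 0")
        if self.beta_dispersion <= 0:
            raise ValueError("beta_dispersion must be > 0")
        if not 0 < self.marker_delta < 1:
            raise ValueError("marker_delta must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohorts"] = [list(c) for c in self.cohorts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cohorts" in d:
            d["cohorts"] = [tuple(c) for c in d["cohorts"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure, for parameter-recovery tests."""

    marker_probe_ids: set = field(default_factory=set)
    cimp_sample_ids: set = field(default_factory=set)
    cimp_extra_ids: set = field(default_factory=set)
    background_hyper_ids: set = field(default_factory=set)
    de_gene_ids: dict = field(default_factory=dict)       # gene -> "up" | "down"
    coupled_pairs: list = field(default_factory=list)     # (probe_id, gene, sign)

    def to_dict(self) -> dict:
        return {
            "marker_probe_ids": sorted(self.marker_probe_ids),
            "cimp_sample_ids": sorted(self.cimp_sample_ids),
            "cimp_extra_ids": sorted(self.cimp_extra_ids),
            "background_hyper_ids": sorted(self.background_hyper_ids),
            "de_gene_ids": self.de_gene_ids,
            "coupled_pairs": [list(p) for p in self.coupled_pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            marker_probe_ids=set(d["marker_probe_ids"]),
            cimp_sample_ids=set(d["cimp_sample_ids"]),
            cimp_extra_ids=set(d["cimp_extra_ids"]),
            background_hyper_ids=set(d["background_hyper_ids"]),
            de_gene_ids=dict(d["de_gene_ids"]),
            coupled_pairs=[tuple(p) for p in d["coupled_pairs"]],
        )


def simulate_annotation(n_probes: int, seed: int, snp_frac: float = 0.05,
                        sex_frac: float = 0.03, n_genes: int = 300) -> pd.DataFrame:
    """Draw a probe manifest: chromosome, position, CGI relation, gene feature, SNP flag.

    Every probe gets exactly one CGI relation and one gene feature
    (``Intergenic`` probes carry no gene symbol).  Positions are 1-based.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not 0 <= snp_frac <= 1 or not 0 <= sex_frac <= 1:
        raise ValueError("snp_frac and sex_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = rng.choice(AUTOSOMES, size=n_probes)
    n_sex = int(round(sex_frac * n_probes))
    if n_sex:
        sex_idx = rng.choice(n_probes, size=n_sex, replace=False)
        chroms[sex_idx] = rng.choice(["chrX", "chrY"], size=n_sex, p=[0.9, 0.1])
    annot = pd.DataFrame({
        "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
        "chrom": chroms,
        "pos": rng.integers(1, 250_000_000, size=n_probes),
        "cgi_relation": rng.choice(CGI_RELATIONS, size=n_probes, p=CGI_PROBS),
        "feature": rng.choice(FEATURES, size=n_probes, p=FEATURE_PROBS),
        "snp": rng.random(n_probes) < snp_frac,
    })
    annot["gene"] = [f"GENE{rng.integers(0, n_genes):04d}" for _ in range(n_probes)]
    annot.loc[annot["feature"] == "Intergenic", "gene"] = pd.NA
    return annot.set_index("probe_id", drop=False)


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cohort, n_t, n_n in config.cohorts:
        n_pairs = min(n_t, n_n)
        for i in range(n_t):
            pid = f"{cohort}_P{i:03d}" if i < n_pairs else f"{cohort}_PT{i:03d}"
            rows.append((f"{cohort}_T{i:03d}", cohort, "tumor", pid))
        for i in range(n_n):
            pid = f"{cohort}_P{i:03d}" if i < n_pairs else f"{cohort}_PN{i:03d}"
            rows.append((f"{cohort}_N{i:03d}", cohort, "adjacent_normal", pid))
    for i in range(config.n_healthy):
        rows.append((f"{config.healthy_cohort}_H{i:03d}", config.healthy_cohort,
                     "healthy", f"{config.healthy_cohort}_P{i:03d}"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "cohort", "tissue", "patient_id"])
    sheet["os_days"] = np.nan
    sheet["os_event"] = np.nan
    return sheet.set_index("sample_id", drop=False)


def _baseline_means(annot: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    # Island/shore probes sit low, open-sea probes high: the bimodal marginal
    # beta distribution typical of 450K arrays.
    n = len(annot)
    mu = np.empty(n)
    island = annot["cgi_relation"].isin(["Island"]).to_numpy()
    shore = annot["cgi_relation"].isin(["NShore", "SShore", "NShelf", "SShelf"]).to_numpy()
    rest = ~(island | shore)
    mu[island] = rng.beta(1.2, 10.0, island.sum())
    mu[shore] = rng.beta(2.0, 6.0, shore.sum())
    mu[rest] = rng.beta(5.0, 2.5, rest.sum())
    return mu


def simulate_cohorts(config: SimulationConfig, annotation: pd.DataFrame):
    """Generate the multi-cohort beta matrix, sample sheet and ground truth.

    Returns ``(beta, sheet, truth)`` where ``beta`` is probes x samples in
    [0, 1], ``sheet`` includes survival fields for target-cohort tumors,
    and ``truth`` records every planted set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    annot = annotation
    probes = annot.index.to_numpy()
    sheet = _sample_frame(config)

    eligible = (annot["chrom"].isin(AUTOSOMES) & ~annot["snp"]).to_numpy()
    promoter = eligible & (annot["feature"] == "TSS200").to_numpy() & annot["gene"].notna().to_numpy()
    promoter_idx = np.flatnonzero(promoter)
    # one marker per gene so cis pairs are unambiguous
    gene_of = annot["gene"].to_numpy()
    seen: set = set()
    marker_pool = []
    for i in rng.permutation(promoter_idx):
        if gene_of[i] not in seen:
            marker_pool.append(i)
            seen.add(gene_of[i])
    if len(marker_pool) < config.n_markers:
        raise ValueError(
            "not enough autosomal SNP-free promoter probes with distinct genes "
            f"to plant {config.n_markers} markers")
    marker_idx = np.array(sorted(marker_pool[:config.n_markers]))

    remaining = np.flatnonzero(eligible & ~np.isin(np.arange(len(probes)), marker_idx))
    n_bg = int(round(config.background_hyper_frac * config.n_probes))
    if config.n_cimp_extra + n_bg > len(remaining):
        raise ValueError("not enough eligible probes for CIMP block and background-hyper set")
    picked = rng.choice(remaining, size=config.n_cimp_extra + n_bg, replace=False)
    cimp_extra_idx = np.sort(picked[:config.n_cimp_extra])
    bg_idx = np.sort(picked[config.n_cimp_extra:])

    mu0 = _baseline_means(annot, rng)
    # marker and CIMP-block probes: essentially unmethylated in normal tissue
    mu0[marker_idx] = rng.uniform(0.02, 0.04, size=len(marker_idx))
    mu0[cimp_extra_idx] = rng.uniform(0.02, 0.04, size=len(cimp_extra_idx))
    mu0[bg_idx] = rng.uniform(0.05, 0.20, size=len(bg_idx))
    if np.any(mu0[marker_idx] + config.marker_delta + config.cimp_delta > 1.0):
        raise ValueError("marker_delta + cimp_delta pushes marker means above 1")

    mu = np.tile(mu0[:, None], (1, len(sheet)))
    tissue = sheet["tissue"].to_numpy()
    cohort = sheet["cohort"].to_numpy()
    is_tumor = tissue == "tumor"
    target_tumor = is_tumor & (cohort == config.target_cohort)

    mu[np.ix_(marker_idx, np.flatnonzero(target_tumor))] += config.marker_delta
    mu[np.ix_(bg_idx, np.flatnonzero(is_tumor))] += config.background_hyper_delta
    # pan-cancer hypervariable block: iid uniform per (probe, tumor sample)
    tum_cols = np.flatnonzero(is_tumor)
    mu[np.ix_(cimp_extra_idx, tum_cols)] += rng.uniform(
        0.0, config.cimp_block_spread, size=(len(cimp_extra_idx), len(tum_cols)))

    target_tumor_ids = sheet.index[target_tumor].to_numpy()
    n_cimp = int(round(config.cimp_fraction * len(target_tumor_ids)))
    cimp_ids = rng.choice(target_tumor_ids, size=n_cimp, replace=False) if n_cimp else np.array([], dtype=object)
    if n_cimp:
        cimp_cols = sheet.index.get_indexer(cimp_ids)
        block_idx = np.concatenate([marker_idx, cimp_extra_idx])
        mu[np.ix_(block_idx, cimp_cols)] += config.cimp_delta

    np.clip(mu, 0.005, 0.995, out=mu)
    kappa = config.beta_dispersion
    beta_vals = rng.beta(mu * kappa, (1.0 - mu) * kappa)
    beta = pd.DataFrame(beta_vals, index=pd.Index(probes, name="probe_id"),
                        columns=sheet.index)

    truth = GroundTruth(
        marker_probe_ids=set(probes[marker_idx]),
        cimp_sample_ids=set(map(str, cimp_ids)),
        cimp_extra_ids=set(probes[cimp_extra_idx]),
        background_hyper_ids=set(probes[bg_idx]),
    )

    surv = simulate_survival(
        sheet.loc[target_tumor_ids], truth.cimp_sample_ids, config.survival_hr,
        censor_rate=config.censor_rate,
        seed=rng.integers(0, 2**31),
        baseline_median_days=config.baseline_median_days)
    sheet.loc[surv.index, ["os_days", "os_event"]] = surv[["os_days", "os_event"]]
    return beta, sheet, truth


def simulate_intensities(beta: pd.DataFrame, scale: float = 1000.0, seed: int = 0,
                         noise_sd: float = 0.0, failed_frac=0.0):
    """Invert the beta ratio into methylated/unmethylated intensities plus detection p-values.

    With ``noise_sd = 0`` the round trip ``beta -> intensities -> beta`` is
    exact (offset 0).  ``failed_frac`` (scalar, or a mapping
    probe_id -> fraction) sets the per-entry rate of failed detection
    (p-value drawn above 0.01).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = np.random.default_rng(seed)
    vals = beta.to_numpy()
    meth = vals * scale
    unmeth = (1.0 - vals) * scale
    if noise_sd > 0:
        meth = np.maximum(meth * (1.0 + rng.normal(0, noise_sd, meth.shape)), 0.0)
        unmeth = np.maximum(unmeth * (1.0 + rng.normal(0, noise_sd, unmeth.shape)), 0.0)
    detp = rng.uniform(0.0, 0.005, size=vals.shape)
    if np.isscalar(failed_frac):
        fail = rng.random(vals.shape) < float(failed_frac)
    else:
        fail = np.zeros(vals.shape, dtype=bool)
        for probe, frac in dict(failed_frac).items():
            row = beta.index.get_loc(probe)
            fail[row] = rng.random(vals.shape[1]) < float(frac)
    detp[fail] = rng.uniform(0.011, 1.0, size=int(fail.sum()))
    as_df = lambda a: pd.DataFrame(a, index=beta.index, columns=beta.columns)
    return as_df(meth), as_df(unmeth), as_df(detp)


def simulate_expression(beta: pd.DataFrame, sheet: pd.DataFrame,
                        annotation: pd.DataFrame, truth: GroundTruth,
                        config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Negative-binomial counts for the target cohort, coupled to marker methylation.

    Marker genes get ``log mean = base + expr_coupling * beta`` at their
    promoter CpG (negative coupling drives expression down in tumors);
    a disjoint set of genes gets an explicit +/- ``de_log2fc`` shift in
    tumors.  Updates ``truth.coupled_pairs`` and ``truth.de_gene_ids``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    keep = sheet["cohort"] == config.target_cohort
    samples = sheet.index[keep]
    is_tumor = (sheet.loc[samples, "tissue"] == "tumor").to_numpy()

    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    base = rng.normal(np.log(500.0), 1.0, size=config.n_genes)
    logmu = np.tile(base[:, None], (1, len(samples)))

    gene_pos = {g: i for i, g in enumerate(genes)}
    sign = -1 if config.expr_coupling < 0 else (1 if config.expr_coupling > 0 else 0)
    truth.coupled_pairs = []
    coupled_genes = set()
    for probe in sorted(truth.marker_probe_ids):
        gene = annotation.loc[probe, "gene"]
        if gene not in gene_pos:
            continue
        logmu[gene_pos[gene]] = base[gene_pos[gene]] + \
            config.expr_coupling * beta.loc[probe, samples].to_numpy()
        truth.coupled_pairs.append((probe, gene, sign))
        coupled_genes.add(gene)

    free = [g for g in genes if g not in coupled_genes]
    n_de = min(config.n_de_genes, len(free))
    de_pick = rng.choice(free, size=n_de, replace=False)
    truth.de_gene_ids = {}
    shift = np.log(2.0) * config.de_log2fc
    for j, gene in enumerate(de_pick):
        d = "up" if j % 2 == 0 else "down"
        truth.de_gene_ids[gene] = d
        logmu[gene_pos[gene], is_tumor] += shift if d == "up" else -shift

    mu = np.exp(logmu)
    size = config.nb_size
    counts = rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)


def simulate_survival(sheet: pd.DataFrame, cimp_ids, hr: float,
                      censor_rate: float = 0.3, seed: int = 0,
                      baseline_median_days: float = 1500.0) -> pd.DataFrame:
    """Exponential proportional-hazards event times with uniform early censoring.

    CIMP samples get hazard ``hr`` times baseline.  A ``censor_rate``
    fraction of samples is censored at a uniform fraction of its event
    time; events are coded 1, censoring 0.
    """
    if hr <= 0:
        raise ValueError("hr must be > 0")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = sheet.copy()
    lam = np.log(2.0) / baseline_median_days
    rate = np.where(out.index.isin(list(cimp_ids)), lam * hr, lam)
    t = rng.exponential(1.0 / rate)
    censored = rng.random(len(out)) < censor_rate
    t = np.where(censored, t * rng.uniform(0.0, 1.0, len(out)), t)
    out["os_days"] = np.maximum(t, 1e-6)
    out["os_event"] = (~censored).astype(int)
    return out
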