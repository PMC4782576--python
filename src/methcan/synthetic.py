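"""Synthetic multi-tissue 450k-style methylation, ChIP-seq and DHS data.

The generator emulates the structure the downstream analysis is designed to
detect: every gene promoter (and its CpG island) carries a latent, largely
tissue-independent propensity u_g to become hypermethylated in cancer, gene
bodies a corresponding propensity to lose methylation; promoter H3K27me3 in
the matched normal tissue increases with u_g while H3K4me3 and gene-body
H3K36me3 decrease with it; expression follows the bivalent promoter marks;
and DNase hypersensitivity of a promoter falls with its normal methylation.

``shared_fraction`` f is the fraction of one tissue's cancer-shift variance
explained by another tissue's shift, i.e. the target cross-tissue R^2.
Since the shift mixes a shared latent u and tissue-specific noise v with
weights (sqrt(rho), sqrt(1-rho)), the cross-tissue Pearson correlation is
rho and R^2 = rho^2; the generator therefore uses rho = sqrt(f).

hESC ("H1") histone tracks are driven by a degraded copy of u_g
(correlation ``rho_hesc``), so marks read out in the matched normal tissue
out-predict the hESC marks by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomicInterval, IntervalSet, ProbeManifest, promoter_window
from .signals import SignalTrack

STATE_NAMES = ("unmethylated", "half", "methylated")


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated compendium.

    Sizes mirror a desk-scale version of the real design: ten fetal tissue
    types as the ground state, six tissue types with matched normal/cancer
    cohorts, and 450k-like probe counts per region.
    """

    n_genes: int = 2000
    n_cgis: int = 1000
    n_tissues: int = 6
    samples_per_phenotype: int = 20   # normal and cancer samples per tissue
    n_fetal_tissues: int = 10
    fetal_samples_per_tissue: int = 2
    probes_per_promoter: int = 3
    probes_per_body: int = 4
    probes_per_cgi: int = 5

    # cancer-shift decomposition
    shared_fraction: float = 0.6      # target cross-tissue R^2 of the shift
    prom_shift_mean: float = 0.25     # mean relative hyper shift at promoters
    prom_shift_sd: float = 0.15
    body_shift_mean: float = 0.25     # mean relative hypo shift at gene bodies
    body_shift_sd: float = 0.15

    # methylation states and probe noise
    state_means: tuple[float, float, float] = (0.1, 0.5, 0.9)
    promoter_state_probs: tuple[float, float, float] = (0.7, 0.1, 0.2)
    body_state_probs: tuple[float, float, float] = (0.15, 0.15, 0.7)
    kappa: float = 50.0               # beta concentration of probe-level noise
    missing_rate: float = 0.02
    low_coverage_fraction: float = 0.02

    # histone couplings to u_g (K27 positive, K4/K36 negative).  H3K4me3
    # additionally loads on the Polycomb (K27) component: bivalent target
    # promoters carry both marks, so K4 is marginally a positive predictor
    # of hypermethylation even though its direct (conditional) effect on
    # the propensity is protective.
    c27: float = 1.2
    c4: float = -1.0
    c36: float = -1.0
    k4_bivalent_coupling: float = 1.5
    k27_baseline: float = 0.0
    k4_baseline: float = 2.0
    k36_baseline: float = 2.0
    histone_noise_sd: float = 0.8
    rho_hesc: float = 0.5

    # expression model (log2 RPKM ~ alpha + b4*s4 - b27*s27 + noise)
    expr_alpha: float = 1.0
    expr_beta4: float = 1.0
    expr_beta27: float = 1.0
    expr_noise_sd: float = 1.0
    zero_rpkm_fraction: float = 0.1

    # DHS coverage: P(covered) = sigmoid(intercept + slope*(beta_normal - 0.5))
    dhs_slope: float = -8.0
    dhs_intercept: float = 0.0

    # genome layout and tracks
    gene_spacing: int = 20_000
    promoter_track_halfwidth: int = 300
    track_bin: int = 50
    dm_top_n: int = 300               # size of the truth DM label sets

    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for name in ("n_genes", "n_cgis", "n_tissues", "samples_per_phenotype",
                     "n_fetal_tissues", "fetal_samples_per_tissue",
                     "probes_per_promoter", "probes_per_body", "probes_per_cgi"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_cgis > self.n_genes:
            raise ValueError("n_cgis cannot exceed n_genes")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]

    @property
    def fetal_tissues(self) -> list[str]:
        return [f"fetal{i:02d}" for i in range(self.n_fetal_tissues)]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests."""

    u: pd.Series                      # shared hypermethylation propensity per gene
    v_promoter: pd.DataFrame          # tissue-specific component, genes x tissues
    v_body: pd.DataFrame
    delta_promoter: pd.DataFrame      # realised cancer-normal shift, genes x tissues
    delta_body: pd.DataFrame
    promoter_state: pd.Series         # ground state per gene promoter
    body_state: pd.Series
    cgi_state: pd.Series              # ground state per CGI
    cgi_host_gene: pd.Series
    dm_truth: dict[str, pd.Index] = field(default_factory=dict)  # tissue -> true DM genes


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneAnnotation]
    manifest: ProbeManifest
    cgis: pd.DataFrame                # cgi_id, chrom, start, end, gene_id
    betas: pd.DataFrame               # probes x all samples
    sample_sheet: pd.DataFrame        # sample, phenotype, tissue
    truth: SyntheticTruth
    tracks: dict[str, dict[str, SignalTrack]]        # source -> mark -> track
    histone_targets: dict[str, pd.DataFrame]         # source -> genes x marks
    expression: pd.Series             # RPKM per gene (H1 reference)
    dhs: dict[str, IntervalSet]       # tissue -> DHS intervals

    def samples(self, phenotype: str, tissue: str | None = None) -> list[str]:
        sel = self.sample_sheet["phenotype"] == phenotype
        if tissue is not None:
            sel &= self.sample_sheet["tissue"] == tissue
        return self.sample_sheet.loc[sel, "sample"].tolist()


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(cfg: SyntheticConfig):
    """Gene models on both strands with 2-6 exons, probes and CGIs.

    Genes are laid out on one chromosome with fixed spacing so promoter
    windows and gene bodies of neighbouring genes never collide.  TSS200
    probes lie within 200 bp upstream of the TSS (strand-aware); Body probes
    lie in non-first exons; CGI probes tile a +/-300 bp island centred on
    the promoters of the first ``n_cgis`` genes.
    """
    rng = cfg.rng(1)
    genes: list[GeneAnnotation] = []
    rows = []
    cgi_rows = []
    margin = 2_000  # keeps promoter windows clear of neighbouring bodies
    for i in range(cfg.n_genes):
        gene_id = f"g{i:05d}"
        left = margin + i * cfg.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 7))
        span = int(rng.integers(4_000, cfg.gene_spacing - 2 * margin))
        # alternating exon/intron blocks, each at least 50 bp
        n_seg = 2 * n_exons - 1
        lengths = 50 + rng.multinomial(span - 50 * n_seg, np.full(n_seg, 1 / n_seg))
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        exons = tuple(
            (left + int(bounds[2 * j]), left + int(bounds[2 * j + 1]))
            for j in range(n_exons)
        )
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        gene = GeneAnnotation(gene_id, "chr1", strand, tss, exons)
        genes.append(gene)

        win = promoter_window(gene, 200, "upstream_only")
        ppos = np.sort(rng.choice(np.arange(win.start, win.end), size=cfg.probes_per_promoter, replace=False))
        for j, pos in enumerate(ppos):
            rows.append((f"{gene_id}_p{j}", "chr1", int(pos), gene_id, "TSS200", ""))

        body_positions = np.concatenate(
            [np.arange(s, e) for s, e in (exons[1:] if strand == "+" else exons[:-1])]
        )
        bpos = np.sort(rng.choice(body_positions, size=cfg.probes_per_body, replace=False))
        for j, pos in enumerate(bpos):
            rows.append((f"{gene_id}_b{j}", "chr1", int(pos), gene_id, "Body", ""))

        if i < cfg.n_cgis:
            cgi_id = f"cgi{i:05d}"
            start, end = max(0, tss - 300), tss + 300
            cgi_rows.append((cgi_id, "chr1", start, end, gene_id))
            cpos = np.sort(rng.choice(np.arange(start, end), size=cfg.probes_per_cgi, replace=False))
            for j, pos in enumerate(cpos):
                rows.append((f"{cgi_id}_c{j}", "chr1", int(pos), "", "", cgi_id))

    manifest = ProbeManifest(
        pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene_id", "region_class", "cgi_id"])
    )
    cgis = pd.DataFrame(cgi_rows, columns=["cgi_id", "chrom", "start", "end", "gene_id"])
    return genes, manifest, cgis


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def generate_methylation(cfg: SyntheticConfig, genes, manifest: ProbeManifest, cgis: pd.DataFrame):
    """Probe-level beta matrices for fetal, normal and cancer phenotypes.

    Fetal and normal region means equal the ground-state mean; the cancer
    mean adds a shift scaled by the available headroom (1 - beta for
    promoter/CGI hypermethylation, beta for gene-body hypomethylation), so
    the shift over a constitutive set is linear in the latent score and the
    cross-tissue correlation structure survives clipping.
    """
    rng = cfg.rng(2)
    gene_ids = pd.Index([g.gene_id for g in genes], name="gene_id")
    n = len(gene_ids)
    state_means = np.asarray(cfg.state_means)

    prom_state = pd.Series(
        rng.choice(3, size=n, p=cfg.promoter_state_probs), index=gene_ids
    )
    body_state = pd.Series(rng.choice(3, size=n, p=cfg.body_state_probs), index=gene_ids)
    cgi_state = prom_state.loc[cgis["gene_id"]].set_axis(cgis["cgi_id"])
    cgi_host = cgis.set_index("cgi_id")["gene_id"]

    # latent decomposition: rho = sqrt(f) so cross-tissue R^2 of the shift = f
    rho = np.sqrt(cfg.shared_fraction)
    u = pd.Series(rng.standard_normal(n), index=gene_ids, name="u")
    v_prom = pd.DataFrame(
        rng.standard_normal((n, cfg.n_tissues)), index=gene_ids, columns=cfg.tissues
    )
    v_body = pd.DataFrame(
        rng.standard_normal((n, cfg.n_tissues)), index=gene_ids, columns=cfg.tissues
    )
    z_prom = np.sqrt(rho) * u.to_numpy()[:, None] + np.sqrt(1 - rho) * v_prom.to_numpy()
    z_body = np.sqrt(rho) * (-u.to_numpy())[:, None] + np.sqrt(1 - rho) * v_body.to_numpy()

    mu_prom_normal = state_means[prom_state.to_numpy()]
    mu_body_normal = state_means[body_state.to_numpy()]
    mu_cgi_normal = state_means[cgi_state.to_numpy()]

    raw_prom = cfg.prom_shift_mean + cfg.prom_shift_sd * z_prom
    raw_body = cfg.body_shift_mean + cfg.body_shift_sd * z_body
    mu_prom_cancer = np.clip(mu_prom_normal[:, None] + (1 - mu_prom_normal)[:, None] * raw_prom, 0, 1)
    mu_body_cancer = np.clip(mu_body_normal[:, None] - mu_body_normal[:, None] * raw_body, 0, 1)
    cgi_to_gene_pos = gene_ids.get_indexer(cgi_host.to_numpy())
    mu_cgi_cancer = np.clip(
        mu_cgi_normal[:, None] + (1 - mu_cgi_normal)[:, None] * raw_prom[cgi_to_gene_pos], 0, 1
    )

    delta_prom = pd.DataFrame(mu_prom_cancer - mu_prom_normal[:, None], index=gene_ids, columns=cfg.tissues)
    delta_body = pd.DataFrame(mu_body_cancer - mu_body_normal[:, None], index=gene_ids, columns=cfg.tissues)

    # per-probe region mean lookup
    t = manifest.table
    probe_ids = t["probe_id"].to_numpy()
    mu_by_probe = {}

    def region_mu(sample_kind: str, tissue_idx: int | None):
        """Vector of probe-level means for one phenotype."""
        mus = np.empty(len(t))
        is_prom = (t["region_class"] == "TSS200").to_numpy()
        is_body = (t["region_class"] == "Body").to_numpy()
        is_cgi = (t["cgi_id"] != "").to_numpy()
        gpos = gene_ids.get_indexer(t["gene_id"].to_numpy())
        cpos = cgi_state.index.get_indexer(t["cgi_id"].to_numpy())
        if sample_kind == "cancer":
            mus[is_prom] = mu_prom_cancer[gpos[is_prom], tissue_idx]
            mus[is_body] = mu_body_cancer[gpos[is_body], tissue_idx]
            mus[is_cgi] = mu_cgi_cancer[cpos[is_cgi], tissue_idx]
        else:
            mus[is_prom] = mu_prom_normal[gpos[is_prom]]
            mus[is_body] = mu_body_normal[gpos[is_body]]
            mus[is_cgi] = mu_cgi_normal[cpos[is_cgi]]
        return mus

    columns, data, sheet_rows = [], [], []

    def add_samples(kind: str, tissue: str, n_samples: int, tissue_idx: int | None):
        mu = np.clip(region_mu(kind, tissue_idx), 1e-3, 1 - 1e-3)
        a, b = mu * cfg.kappa, (1 - mu) * cfg.kappa
        for s in range(n_samples):
            name = f"{kind}_{tissue}_{s:02d}"
            data.append(rng.beta(a, b))
            columns.append(name)
            sheet_rows.append((name, kind, tissue))

    for tissue in cfg.fetal_tissues:
        add_samples("fetal", tissue, cfg.fetal_samples_per_tissue, None)
    for ti, tissue in enumerate(cfg.tissues):
        add_samples("normal", tissue, cfg.samples_per_phenotype, ti)
        add_samples("cancer", tissue, cfg.samples_per_phenotype, ti)

    betas = pd.DataFrame(np.column_stack(data), index=pd.Index(probe_ids, name="probe_id"), columns=columns)

    # missingness: MCAR entries plus a handful of low-coverage probes
    missing = rng.random(betas.shape) < cfg.missing_rate
    low_cov = rng.random(len(betas)) < cfg.low_coverage_fraction
    lc_rate = rng.uniform(0.35, 0.6, size=int(low_cov.sum()))
    missing[low_cov] |= rng.random((int(low_cov.sum()), betas.shape[1])) < lc_rate[:, None]
    betas = betas.mask(missing)

    sheet = pd.DataFrame(sheet_rows, columns=["sample", "phenotype", "tissue"])

    # truth DM labels: top-shift genes among ground-state-unmethylated promoters
    dm_truth = {}
    unmeth = prom_state.index[prom_state == 0]
    for tissue in cfg.tissues:
        dm_truth[tissue] = (
            delta_prom.loc[unmeth, tissue].sort_values(ascending=False).index[: cfg.dm_top_n]
        )

    truth = SyntheticTruth(
        u=u,
        v_promoter=v_prom,
        v_body=v_body,
        delta_promoter=delta_prom,
        delta_body=delta_body,
        promoter_state=prom_state,
        body_state=body_state,
        cgi_state=cgi_state,
        cgi_host_gene=cgi_host,
        dm_truth=dm_truth,
    )
    return betas, sheet, truth


# ---------------------------------------------------------------------------
# Histone tracks, expression, DHS
# ---------------------------------------------------------------------------

def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _tile(iv_start: int, iv_end: int, value: float, bin_size: int):
    edges = list(range(iv_start, iv_end, bin_size)) + [iv_end]
    return [(edges[i], edges[i + 1], value) for i in range(len(edges) - 1)]


def generate_histone_tracks(cfg: SyntheticConfig, truth: SyntheticTruth, genes):
    """bedGraph tracks per tissue and for the hESC reference.

    Per-gene targets: s27 rises with u_g, s4 and s36 fall with it (softplus
    keeps S >= 0).  K4/K27 tiles cover the +/-300 bp promoter window, K36
    the gene body including introns; each gene's tiles carry its constant
    target value, so averaging the track over the region recovers the
    target exactly up to tiles extending past the window edge.
    """
    rng = cfg.rng(3)
    gene_ids = truth.u.index
    u = truth.u.to_numpy()
    u_hesc = cfg.rho_hesc * u + np.sqrt(1 - cfg.rho_hesc**2) * rng.standard_normal(len(u))

    sources = {t: u for t in cfg.tissues}
    sources["hESC"] = u_hesc

    tracks: dict[str, dict[str, SignalTrack]] = {}
    targets: dict[str, pd.DataFrame] = {}
    for source, latent in sources.items():
        eps = rng.normal(0, cfg.histone_noise_sd, size=(len(u), 3))
        k27_core = cfg.c27 * latent + eps[:, 0]
        s27 = _softplus(k27_core + cfg.k27_baseline)
        s4 = _softplus(
            cfg.k4_bivalent_coupling * k27_core + cfg.c4 * latent + cfg.k4_baseline + eps[:, 1]
        )
        s36 = _softplus(cfg.c36 * latent + cfg.k36_baseline + eps[:, 2])
        targets[source] = pd.DataFrame(
            {"H3K4me3": s4, "H3K27me3": s27, "H3K36me3": s36}, index=gene_ids
        )
        per_mark: dict[str, SignalTrack] = {}
        for mark in ("H3K4me3", "H3K27me3", "H3K36me3"):
            chroms, starts, ends, values = [], [], [], []
            for g, val in zip(genes, targets[source][mark].to_numpy()):
                if mark == "H3K36me3":
                    span = g.body_span
                    region = (span.start, span.end)
                else:
                    w = cfg.promoter_track_halfwidth
                    region = (max(0, g.tss - w), g.tss + w)
                for s, e, v in _tile(region[0], region[1], float(val), cfg.track_bin):
                    chroms.append(g.chrom)
                    starts.append(s)
                    ends.append(e)
                    values.append(v)
            per_mark[mark] = SignalTrack(chroms, starts, ends, values)
        tracks[source] = per_mark
    return tracks, targets


def generate_expression(cfg: SyntheticConfig, hesc_targets: pd.DataFrame) -> pd.Series:
    """RPKM vector coupled to the reference-line promoter marks."""
    rng = cfg.rng(4)
    log2 = (
        cfg.expr_alpha
        + cfg.expr_beta4 * hesc_targets["H3K4me3"]
        - cfg.expr_beta27 * hesc_targets["H3K27me3"]
        + rng.normal(0, cfg.expr_noise_sd, size=len(hesc_targets))
    )
    rpkm = np.power(2.0, log2)
    zero = rng.random(len(rpkm)) < cfg.zero_rpkm_fraction
    rpkm[zero] = 0.0
    return pd.Series(rpkm, index=hesc_targets.index, name="rpkm")


def generate_dhs(
    cfg: SyntheticConfig, normal_promoter_beta: pd.Series, genes
) -> dict[str, IntervalSet]:
    """Per-tissue DHS interval sets covering promoters of open chromatin.

    A promoter is covered with probability sigmoid(intercept + slope *
    (beta_normal - 0.5)); the default negative slope makes coverage fall
    with normal methylation.
    """
    rng = cfg.rng(5)
    beta = normal_promoter_beta.reindex([g.gene_id for g in genes]).to_numpy()
    logit = cfg.dhs_intercept + cfg.dhs_slope * (beta - 0.5)
    prob = 1.0 / (1.0 + np.exp(-logit))
    out = {}
    for tissue in cfg.tissues:
        covered = rng.random(len(genes)) < prob
        ivs = IntervalSet()
        for g, c in zip(genes, covered):
            if c:
                w = cfg.promoter_track_halfwidth
                ivs.add(GenomicInterval(g.chrom, max(0, g.tss - w), g.tss + w))
        out[tissue] = ivs
    return out


def generate_all(cfg: SyntheticConfig) -> SyntheticDataset:
    """Run every generator stage with seeds derived from cfg.seed."""
    genes, manifest, cgis = generate_annotation(cfg)
    betas, sheet, truth = generate_methylation(cfg, genes, manifest, cgis)
    tracks, targets = generate_histone_tracks(cfg, truth, genes)
    expression = generate_expression(cfg, targets["hESC"])
    state_means = np.asarray(cfg.state_means)
    normal_prom = pd.Series(
        state_means[truth.promoter_state.to_numpy()], index=truth.promoter_state.index
    )
    dhs = generate_dhs(cfg, normal_prom, genes)
    return SyntheticDataset(
        config=cfg,
        genes=genes,
        manifest=manifest,
        cgis=cgis,
        betas=betas,
        sample_sheet=sheet,
        truth=truth,
        tracks=tracks,
        histone_targets=targets,
        expression=expression,
        dhs=dhs,
    )
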