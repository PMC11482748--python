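"""Multi-study synthetic fixtures with known ground truth.

Emulates the statistical structure of a five-cohort supervised-loading
programme: 144 participants (studies of 32/33/47/20/12 subjects, one MRI
cohort), paired pre/post muscle transcriptome profiles, and a baseline
panel of bulk profiles composed as convex mixtures of cell-type
signatures. The percent change in lean mass follows a two-component
truncated normal (responders mean +6.6 sd 3.9 truncated above the 2.5%
instrument threshold; non-responders mean -0.6 sd 1.8 truncated below
2.0%), so latent labels are unambiguous; a configurable handful of
subjects sit inside the precision gray zone. Effects are planted on
known genes:

* group-specific differential expression — a fixed log2 shift applied
  post-training in one responder group only;
* linear association — post-training change beta * %dLLM with beta solved
  in closed form so the per-gene Pearson r hits a target;
* cell-type signatures — mixture-matrix genes driven by one cell
  population's fraction.

Everything is seeded; a fixed config yields byte-identical outputs. Each
generator draws from its own seed substream, so generators are
deterministic independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PairedExpressionSet
from .phenotyping import INDETERMINATE, LMR, NMLMR

# printed post-filter gene counts per biotype, used as default proportions
BIOTYPE_COUNTS = {
    "protein_coding": 13249,
    "lncRNA": 7173,
    "miscRNA": 1192,
    "pseudogene": 1254,
}
NCRNA_BIOTYPES = ("lncRNA", "miscRNA", "pseudogene")

DEFAULT_CELL_FRACTIONS = {
    "type_I_fibre": 0.35,
    "type_II_fibre": 0.45,
    "satellite": 0.04,
    "endothelial": 0.08,
    "pericyte": 0.03,
    "macrophage": 0.03,
    "t_cell": 0.015,
    "b_cell": 0.005,
}


def _default_biotype_fractions() -> dict[str, float]:
    total = sum(BIOTYPE_COUNTS.values())
    return {k: v / total for k, v in BIOTYPE_COUNTS.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0
    study_sizes: tuple[int, ...] = (32, 33, 47, 20, 12)
    modality_per_study: tuple[str, ...] = ("DXA", "DXA", "DXA", "MRI", "DXA")
    n_genes: int = sum(BIOTYPE_COUNTS.values())  # 22868, the post-filter universe
    biotype_fractions: dict[str, float] = field(default_factory=_default_biotype_fractions)
    # latent phenotype composition (88 + 50 + 6 = 144)
    n_responders: int = 88
    n_non_responders: int = 50
    n_indeterminate: int = 6
    responder_mean_sd: tuple[float, float] = (6.6, 3.9)
    non_responder_mean_sd: tuple[float, float] = (-0.6, 1.8)
    # planted effects
    n_planted_lmr_de: int = 50
    n_planted_nmlmr_de: int = 15
    n_planted_linear: int = 46
    planted_overlap: int = 1
    effect_size_log2: float = 0.5
    linear_r_target: float = 0.3
    noise_sd_log2: float = 0.35
    subject_icc: float = 0.5
    # baseline mixture panel
    n_mixture_samples: int = 437
    cell_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_FRACTIONS)
    )
    dirichlet_concentration: float = 30.0
    mixture_signal_scale: float = 1.5
    mixture_noise_sd: float = 0.1
    n_signature_genes_per_type: int = 10

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.study_sizes):
            raise ValueError("study sizes must all be positive")
        if len(self.modality_per_study) != len(self.study_sizes):
            raise ValueError("one modality per study is required")
        if abs(sum(self.biotype_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("biotype fractions must sum to 1")
        if abs(sum(self.cell_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("cell fractions must sum to 1")
        total = self.n_responders + self.n_non_responders + self.n_indeterminate
        if total != sum(self.study_sizes):
            raise ValueError(
                f"latent class counts ({total}) must sum to the number of "
                f"subjects ({sum(self.study_sizes)})"
            )
        n_planted = (
            self.n_planted_lmr_de
            + self.n_planted_nmlmr_de
            + self.n_planted_linear
            - self.planted_overlap
        )
        if n_planted > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.planted_overlap > min(self.n_planted_lmr_de, self.n_planted_linear):
            raise ValueError("planted_overlap exceeds the planted set sizes")
        if not (0.0 <= self.subject_icc < 1.0):
            raise ValueError("subject_icc must be in [0, 1)")
        if not (0.0 <= self.linear_r_target < 1.0):
            raise ValueError("linear_r_target must be in [0, 1)")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted truth for verification of every downstream stage."""

    planted_lmr_de: set[str] = field(default_factory=set)
    planted_nmlmr_de: set[str] = field(default_factory=set)
    planted_linear: set[str] = field(default_factory=set)
    true_labels: dict[str, str] = field(default_factory=dict)
    cell_signature_genes: dict[str, set[str]] = field(default_factory=dict)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# seed substreams per generator
_STREAM_COHORTS = 1
_STREAM_ANNOTATION = 2
_STREAM_EXPRESSION = 3
_STREAM_MIXTURE = 4
_STREAM_MODULES = 5


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation table (gene_id, symbol, biotype), deterministic in seed.

    Biotype counts follow the configured fractions by largest remainder;
    marker symbols from the curated muscle panel are carried by randomly
    chosen protein-coding genes so the mixture panel can resolve them.
    """
    from .celltype import DEFAULT_MARKERS

    rng = _rng(config, _STREAM_ANNOTATION)
    fractions = config.biotype_fractions
    raw = {b: f * config.n_genes for b, f in fractions.items()}
    counts = {b: int(np.floor(v)) for b, v in raw.items()}
    remainder = config.n_genes - sum(counts.values())
    by_frac = sorted(raw, key=lambda b: raw[b] - np.floor(raw[b]), reverse=True)
    for b in by_frac[:remainder]:
        counts[b] += 1
    biotypes = np.array(
        [b for b, c in sorted(counts.items()) for _ in range(c)], dtype=object
    )
    rng.shuffle(biotypes)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    ann = pd.DataFrame(
        {"symbol": [f"SYM_{g}" for g in gene_ids], "biotype": biotypes},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    pc = ann.index[ann["biotype"] == "protein_coding"].to_numpy()
    marker_symbols = [s for syms in DEFAULT_MARKERS.values() for s in syms]
    hosts = rng.choice(pc, size=len(marker_symbols), replace=False)
    ann.loc[hosts, "symbol"] = marker_symbols
    return ann


def generate_cohorts(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Phenotype table for all studies plus the latent true labels.

    Returns (phenotypes, true_labels): phenotypes has one row per subject
    with subject_id, study_id, modality, llm_pre, llm_post and the latent
    pct drawn from the truncated two-component model.
    """
    rng = _rng(config, _STREAM_COHORTS)
    n_total = sum(config.study_sizes)
    labels = np.array(
        [LMR] * config.n_responders
        + [NMLMR] * config.n_non_responders
        + [INDETERMINATE] * config.n_indeterminate,
        dtype=object,
    )
    rng.shuffle(labels)

    mu_r, sd_r = config.responder_mean_sd
    mu_n, sd_n = config.non_responder_mean_sd
    pct = np.empty(n_total)
    for i, lab in enumerate(labels):
        if lab == LMR:
            a = (2.5 - mu_r) / sd_r if sd_r > 0 else -np.inf
            pct[i] = (
                stats.truncnorm.rvs(a, np.inf, loc=mu_r, scale=sd_r, random_state=rng)
                if sd_r > 0
                else max(mu_r, 2.5)
            )
        elif lab == NMLMR:
            b = (2.0 - mu_n) / sd_n if sd_n > 0 else np.inf
            pct[i] = (
                stats.truncnorm.rvs(-np.inf, b, loc=mu_n, scale=sd_n, random_state=rng)
                if sd_n > 0
                else min(mu_n, 2.0 - 1e-9)
            )
        else:
            pct[i] = rng.uniform(2.0, 2.5)
    # nudge any draw that rounds onto a boundary the wrong way
    pct = np.where(labels == NMLMR, np.minimum(pct, np.nextafter(2.0, -np.inf)), pct)

    study_ids, modalities = [], []
    for size, (s_idx, modality) in zip(
        config.study_sizes, enumerate(config.modality_per_study)
    ):
        study_ids += [f"study{s_idx + 1}"] * size
        modalities += [modality] * size
    subject_ids = [f"sub{i:03d}" for i in range(n_total)]
    llm_pre = rng.normal(8.0, 1.0, size=n_total).clip(min=3.0)
    llm_post = llm_pre * (1.0 + pct / 100.0)
    phenotypes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "study_id": study_ids,
            "modality": modalities,
            "llm_pre": llm_pre,
            "llm_post": llm_post,
        }
    )
    true_labels = dict(zip(subject_ids, labels))
    return phenotypes, true_labels


def generate_expression(
    cohorts: pd.DataFrame,
    config: SimulationConfig,
    true_labels: dict[str, str],
    annotation: pd.DataFrame | None = None,
) -> tuple[PairedExpressionSet, GroundTruth]:
    """Paired pre/post log2 profiles with planted DE and linear effects.

    Measurement model per subject i, gene g:
        pre  = mu_g + a_ig + e,   post = mu_g + a_ig + e' + effect_ig
    with a ~ N(0, sd*sqrt(icc)) shared within subject and
    e ~ N(0, sd*sqrt(1-icc)), so paired differences have noise sd
    sqrt(2)*sd*sqrt(1-icc). DE effects shift planted genes by
    ``effect_size_log2`` in one latent group only; linear genes add
    beta * %dLLM with beta = r/sqrt(1-r^2) * sd_delta / sd_pct.
    """
    if annotation is None:
        annotation = generate_annotation(config)
    rng = _rng(config, _STREAM_EXPRESSION)
    genes = annotation.index.to_numpy()
    ncrna = annotation.index[annotation["biotype"].isin(NCRNA_BIOTYPES)].to_numpy()
    n_planted = (
        config.n_planted_lmr_de + config.n_planted_nmlmr_de + config.n_planted_linear
        - config.planted_overlap
    )
    if n_planted > len(ncrna):
        raise ValueError("not enough ncRNA genes to hold the planted sets")
    picked = rng.choice(ncrna, size=n_planted, replace=False)
    lmr_de = set(picked[: config.n_planted_lmr_de])
    nmlmr_de = set(
        picked[config.n_planted_lmr_de: config.n_planted_lmr_de + config.n_planted_nmlmr_de]
    )
    overlap = set(picked[: config.planted_overlap])  # shared LMR-DE / linear genes
    fresh_linear = picked[config.n_planted_lmr_de + config.n_planted_nmlmr_de:]
    linear = overlap | set(fresh_linear)

    subjects = cohorts["subject_id"].tolist()
    pct = (
        100.0
        * (cohorts["llm_post"] - cohorts["llm_pre"])
        / cohorts["llm_pre"]
    ).to_numpy()
    n_sub = len(subjects)
    n_genes = len(genes)

    sd_b = config.noise_sd_log2 * np.sqrt(config.subject_icc)
    sd_w = config.noise_sd_log2 * np.sqrt(1.0 - config.subject_icc)
    mu = rng.normal(7.0, 1.5, size=n_genes)
    # scale-0 normals are exact zeros, so the noiseless case stays on the
    # same code path (and consumes the same stream)
    subj_eff = rng.normal(0.0, sd_b, size=(n_genes, n_sub))
    e_pre = rng.normal(0.0, sd_w, size=(n_genes, n_sub))
    e_post = rng.normal(0.0, sd_w, size=(n_genes, n_sub))

    effect = np.zeros((n_genes, n_sub))
    gene_pos = {g: i for i, g in enumerate(genes)}
    labels_arr = np.array([true_labels[s] for s in subjects], dtype=object)
    lmr_mask = labels_arr == LMR
    nmlmr_mask = labels_arr == NMLMR
    for g in lmr_de:
        effect[gene_pos[g], lmr_mask] += config.effect_size_log2
    for g in nmlmr_de:
        effect[gene_pos[g], nmlmr_mask] += config.effect_size_log2

    sd_delta = np.sqrt(2.0) * sd_w
    sd_pct = float(np.std(pct, ddof=1))
    r = config.linear_r_target
    beta = (r / np.sqrt(1.0 - r**2)) * sd_delta / sd_pct if sd_pct > 0 else 0.0
    for g in linear:
        effect[gene_pos[g], :] += beta * pct

    pre = mu[:, None] + subj_eff + e_pre
    post = mu[:, None] + subj_eff + e_post + effect

    sample_ids = [f"{s}_pre" for s in subjects] + [f"{s}_post" for s in subjects]
    values = pd.DataFrame(
        np.hstack([pre, post]), index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )
    samples = pd.DataFrame(
        {
            "subject_id": subjects * 2,
            "study_id": cohorts["study_id"].tolist() * 2,
            "timepoint": ["pre"] * n_sub + ["post"] * n_sub,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        planted_lmr_de=lmr_de,
        planted_nmlmr_de=nmlmr_de,
        planted_linear=linear,
        true_labels=dict(true_labels),
    )
    expr = PairedExpressionSet(values, samples, annotation)
    return expr, truth


def generate_marker_mixture(
    config: SimulationConfig,
    annotation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Baseline panel of bulk profiles as convex cell-type mixtures.

    Per-sample cell fractions are Dirichlet-distributed around the
    configured composition. A gene in cell type c's signature reads
    base_g + scale * f_cs / mean_c + noise, i.e. its signal tracks the
    fold-deviation of that population's fraction, so rare populations are
    as recoverable as abundant ones. Marker genes (resolved through the
    annotation) belong to exactly one signature.
    """
    from .celltype import DEFAULT_MARKERS

    if annotation is None:
        annotation = generate_annotation(config)
    rng = _rng(config, _STREAM_MIXTURE)
    cell_types = list(config.cell_fractions)
    base_fracs = np.array([config.cell_fractions[c] for c in cell_types])
    fractions = rng.dirichlet(
        config.dirichlet_concentration * base_fracs, size=config.n_mixture_samples
    ).T  # (n_types, n_samples)

    sym_to_id = dict(zip(annotation["symbol"], annotation.index))
    signature: dict[str, set[str]] = {}
    taken: set[str] = set()
    for ct in cell_types:
        marker_ids = {
            sym_to_id[s] for s in DEFAULT_MARKERS.get(ct, ()) if s in sym_to_id
        }
        signature[ct] = set(marker_ids)
        taken |= marker_ids
    free = annotation.index[~annotation.index.isin(sorted(taken))].to_numpy()
    extras = rng.choice(
        free, size=config.n_signature_genes_per_type * len(cell_types), replace=False
    )
    for i, ct in enumerate(cell_types):
        chunk = extras[
            i * config.n_signature_genes_per_type: (i + 1) * config.n_signature_genes_per_type
        ]
        signature[ct] |= set(chunk)

    genes = annotation.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    base = rng.normal(6.0, 1.0, size=len(genes))
    x = np.tile(base[:, None], (1, config.n_mixture_samples))
    for ci, ct in enumerate(cell_types):
        rel = fractions[ci] / base_fracs[ci]
        for g in sorted(signature[ct]):
            x[gene_pos[g]] += config.mixture_signal_scale * rel
    if config.mixture_noise_sd > 0:
        x += rng.normal(0.0, config.mixture_noise_sd, size=x.shape)
    matrix = pd.DataFrame(
        x,
        index=pd.Index(genes, name="gene_id"),
        columns=[f"base{j:03d}" for j in range(config.n_mixture_samples)],
    )
    return matrix, signature


def generate_modules_and_genesets(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    signature_genes: dict[str, set[str]],
    planted_de: set[str],
) -> tuple[dict[str, set[str]], dict[str, list[str]], set[str]]:
    """Synthetic co-expression modules, GMT gene sets and background.

    One module per cell type, seeded with that type's mixture-signature
    genes, a block of protein-coding genes shared with a matching GMT term
    (so the term is strongly over-represented) and a couple of planted DE
    genes (so modules contain hypertrophy-signature members). Null terms
    of random background genes are added as negative controls.
    """
    rng = _rng(config, _STREAM_MODULES)
    background = set(annotation.index[annotation["biotype"] == "protein_coding"])
    pc = np.array(sorted(background))
    planted = sorted(planted_de)
    modules: dict[str, set[str]] = {}
    gene_sets: dict[str, list[str]] = {}
    for i, (ct, sig) in enumerate(sorted(signature_genes.items())):
        core = set(rng.choice(pc, size=30, replace=False))
        seeds = set(rng.choice(planted, size=min(2, len(planted)), replace=False))
        modules[f"module_{ct}"] = sig | core | seeds
        spill = set(rng.choice(pc, size=70, replace=False))
        gene_sets[f"TERM_{ct.upper()}"] = sorted(core | spill)
    for j in range(5):
        gene_sets[f"TERM_NULL_{j}"] = sorted(rng.choice(pc, size=100, replace=False))
    return modules, gene_sets, background
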