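"""Seeded simulation engine for the multi-ethnic type-I-error and power study.

A synthetic cohort of 10 HapMap-labelled populations (2000 individuals
each, 20 000 total) spanning African, East Asian, South Asian, Hispanic and
European ancestry is generated under the Balding-Nichols model: each SNP's
per-population allele frequency is a Beta draw around an ancestral
frequency with differentiation parameter F, hierarchically (ancestral ->
continental block -> population), and the five admixed populations (ASW,
MKK, LWK, MXL, GIH) mix their own frequency with a second ancestral block
according to Beta-distributed individual admixture proportions.  This
replaces haplotype-resampling from reference panels while preserving the
continental structure that PCA must detect.

Population structure is confounded with the phenotype by varying the
case:control ratio across populations at fixed total sample size
("moderate" and "extreme" configurations).  Causal-SNP genotypes are drawn
retrospectively: controls from Hardy-Weinberg proportions at the population
frequency, cases with genotype odds multiplied by OR^g (optionally with an
exact-prevalence intercept instead of the rare-disease approximation).

Heterogeneity models for the causal allelic effect (log-odds ratio):
``null`` (0 everywhere), ``homogeneous`` (+b everywhere),
``african_specific`` (+b in the four African-ancestry populations only),
``african_vs_others`` (+b African, -b elsewhere) and
``eastasian_vs_others`` (+b East Asian, -b European/South Asian/Hispanic,
0 African).

Each replicate re-draws the causal SNP and is analysed by the pooled
AGV-adjusted logistic LRT, the unadjusted LRT, the 2-df SNP x AGV
interaction test, and per-population association combined by fixed-effects
inverse-variance meta-analysis with Cochran's Q.  Everything is reproducible
from a single master seed via per-replicate substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .assoc import fit_logistic, lrt_pvalue
from .geno_io import GenotypeMatrix, ValidationError, VariantRecord
from .meta import cochran_q, ivw_meta
from .structure import compute_agv_from_genotypes

# ---------------------------------------------------------------------------
# scenario definition

#: population roster with continental-ancestry tags
POPULATIONS: tuple = (
    ("MKK", "African"),
    ("ASW", "African"),
    ("LWK", "African"),
    ("YRI", "African"),
    ("CHB/JPT", "EastAsian"),
    ("CHD", "EastAsian"),
    ("GIH", "SouthAsian"),
    ("MXL", "Hispanic"),
    ("CEU", "European"),
    ("TSI", "European"),
)

#: admixed populations and the second ancestral block they draw from
ADMIXED: dict = {
    "MKK": "European",
    "ASW": "European",
    "LWK": "European",
    "MXL": "European",
    "GIH": "European",
}

MODELS = (
    "null", "homogeneous", "african_specific", "african_vs_others",
    "eastasian_vs_others",
)
STRUCTURES = ("none", "moderate", "extreme")
ANALYSES = (
    "glm_agv", "glm_unadjusted", "meta_fixed", "het_interaction", "het_cochran_q",
)

# per-ancestry-block case fractions; totals are fixed at half the cohort
_CASE_FRACTIONS = {
    "none": {
        "African": 0.5, "EastAsian": 0.5, "SouthAsian": 0.5,
        "Hispanic": 0.5, "European": 0.5,
    },
    "moderate": {
        "African": 0.35, "EastAsian": 0.65, "SouthAsian": 0.45,
        "Hispanic": 0.55, "European": 0.65,
    },
    "extreme": {
        "African": 0.0, "EastAsian": 5 / 6, "SouthAsian": 5 / 6,
        "Hispanic": 5 / 6, "European": 5 / 6,
    },
}


@dataclass
class FrequencyModel:
    """Balding-Nichols frequency hierarchy.

    The ancestral frequency is uniform on ``base_freq_range``; continental
    block frequencies differentiate from it with ``F_block`` (African
    lineages are the most diverged), populations within a block with
    ``F_within``.  Admixture proportions of admixed-population individuals
    toward their own block follow ``Beta(*admixture_beta)``.
    """

    base_freq_range: tuple = (0.1, 0.9)
    F_block: dict = field(
        default_factory=lambda: {
            "African": 0.15, "EastAsian": 0.10, "SouthAsian": 0.10,
            "Hispanic": 0.10, "European": 0.10,
        }
    )
    F_within: float = 0.02
    admixture_beta: tuple = (8.0, 2.0)
    clip: tuple = (0.01, 0.99)


@dataclass
class SimulationScenario:
    """One cell of the simulation design."""

    model: str = "null"
    structure: str = "none"
    effect_size: float = 0.0  # |log-OR| assigned per the heterogeneity model
    populations: tuple = POPULATIONS
    pop_size: int = 2000
    case_fractions: dict = field(default_factory=dict)  # per population
    log_ors: dict = field(default_factory=dict)  # per population
    freq: FrequencyModel = field(default_factory=FrequencyModel)
    n_background_snps: int = 24000
    n_multiethnic_agv: int = 10
    n_pop_agv: int = 4
    n_replicates: int = 1000
    thresholds: tuple = (0.05, 0.01, 5e-8)
    prevalence: Optional[float] = None  # exact-prevalence sampling when set

    def __post_init__(self):
        if self.pop_size < 1:
            raise ValidationError("pop_size must be positive")
        for pop, _ in self.populations:
            cf = self.case_fractions.get(pop, 0.5)
            if not (0.0 <= cf <= 1.0):
                raise ValidationError(f"case fraction for {pop} outside [0,1]")

    @property
    def pop_names(self) -> list:
        return [p for p, _ in self.populations]

    @property
    def ancestry(self) -> dict:
        return dict(self.populations)

    @property
    def n_total(self) -> int:
        return self.pop_size * len(self.populations)

    def n_cases(self, pop: str) -> int:
        return int(round(self.case_fractions.get(pop, 0.5) * self.pop_size))

    def labels(self) -> np.ndarray:
        return np.repeat(self.pop_names, self.pop_size)

    def phenotype(self) -> np.ndarray:
        """Fixed phenotype vector: within each population, cases first."""
        parts = []
        for pop in self.pop_names:
            nc = self.n_cases(pop)
            parts.append(np.r_[np.ones(nc), np.zeros(self.pop_size - nc)])
        return np.concatenate(parts).astype(int)


def make_scenario(
    model: str, structure: str, effect_size: float = 0.0, **overrides
) -> SimulationScenario:
    """Build a scenario with per-population log-ORs filled in from the
    heterogeneity model and case fractions from the structure level."""
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")
    if structure not in STRUCTURES:
        raise ValidationError(
            f"unknown structure {structure!r}; choose from {STRUCTURES}"
        )
    b = float(effect_size)
    ancestry = dict(POPULATIONS)
    pops = [p for p, _ in POPULATIONS]
    if model == "null":
        log_ors = {p: 0.0 for p in pops}
    elif model == "homogeneous":
        log_ors = {p: b for p in pops}
    elif model == "african_specific":
        log_ors = {p: (b if ancestry[p] == "African" else 0.0) for p in pops}
    elif model == "african_vs_others":
        log_ors = {p: (b if ancestry[p] == "African" else -b) for p in pops}
    else:  # eastasian_vs_others
        log_ors = {
            p: (
                b
                if ancestry[p] == "EastAsian"
                else (0.0 if ancestry[p] == "African" else -b)
            )
            for p in pops
        }
    fractions = {p: _CASE_FRACTIONS[structure][ancestry[p]] for p in pops}
    return SimulationScenario(
        model=model,
        structure=structure,
        effect_size=b,
        case_fractions=fractions,
        log_ors=log_ors,
        **overrides,
    )


def scenario_from_dict(cfg: dict) -> SimulationScenario:
    """Build a scenario from a parsed YAML/JSON config mapping."""
    cfg = dict(cfg)
    # YAML reads the bare word `null` as None; it names the no-effect model
    model = cfg.pop("model", "null") or "null"
    structure = cfg.pop("structure", "none") or "none"
    effect = cfg.pop("effect_size", 0.0)
    if "freq" in cfg and isinstance(cfg["freq"], dict):
        fm = cfg["freq"]
        for key in ("base_freq_range", "admixture_beta", "clip"):
            if key in fm:
                fm[key] = tuple(fm[key])
        cfg["freq"] = FrequencyModel(**fm)
    if "populations" in cfg:
        cfg["populations"] = tuple(tuple(pair) for pair in cfg["populations"])
    if "thresholds" in cfg:
        cfg["thresholds"] = tuple(cfg["thresholds"])
    return make_scenario(model, structure, effect, **cfg)


# ---------------------------------------------------------------------------
# frequency and genotype generation

def draw_frequencies(base_freq: float, F_per_pop, rng, clip=(0.01, 0.99)):
    """Balding-Nichols per-population frequency draws around ``base_freq``.

    Population i draws Beta(p(1-F_i)/F_i, (1-p)(1-F_i)/F_i); F_i = 0 pins
    the frequency at ``base_freq`` exactly.  Results are clipped to
    ``clip`` so no population is degenerate.
    """
    if not (0.0 < base_freq < 1.0):
        raise ValidationError("base_freq must lie in (0, 1)")
    F = np.asarray(F_per_pop, dtype=float)
    if (F < 0).any() or (F >= 1).any():
        raise ValidationError("F values must lie in [0, 1)")
    out = np.empty(F.shape)
    zero = F == 0
    out[zero] = base_freq
    if (~zero).any():
        Fz = F[~zero]
        a = base_freq * (1.0 - Fz) / Fz
        b = (1.0 - base_freq) * (1.0 - Fz) / Fz
        out[~zero] = rng.beta(a, b)
    return np.clip(out, clip[0], clip[1])


def _bn_draw(base: np.ndarray, F: float, rng, clip) -> np.ndarray:
    """Vectorised Balding-Nichols draw around per-SNP base frequencies."""
    if F == 0.0:
        return base.copy()
    a = base * (1.0 - F) / F
    b = (1.0 - base) * (1.0 - F) / F
    return np.clip(rng.beta(a, b), clip[0], clip[1])


def _draw_hierarchical_freqs_batch(scenario: SimulationScenario, n_snps: int, rng):
    """Frequencies for a batch of SNPs: ancestral -> block -> population.

    Returns (block_freqs, pop_freqs) as dicts of length-``n_snps`` arrays.
    """
    fm = scenario.freq
    lo, hi = fm.base_freq_range
    p0 = rng.uniform(lo, hi, size=n_snps)
    blocks = list(dict.fromkeys(anc for _, anc in scenario.populations))
    block_freqs = {
        b: _bn_draw(p0, fm.F_block[b], rng, fm.clip) for b in blocks
    }
    pop_freqs = {
        pop: _bn_draw(block_freqs[anc], fm.F_within, rng, fm.clip)
        for pop, anc in scenario.populations
    }
    return block_freqs, pop_freqs


def _draw_hierarchical_freqs(scenario: SimulationScenario, rng):
    """One SNP's frequencies as scalars (see the batch variant)."""
    block_freqs, pop_freqs = _draw_hierarchical_freqs_batch(scenario, 1, rng)
    return (
        {b: float(v[0]) for b, v in block_freqs.items()},
        {p: float(v[0]) for p, v in pop_freqs.items()},
    )


def draw_admixture(scenario: SimulationScenario, rng) -> dict:
    """Per-individual admixture proportions toward the population's own
    ancestral block, for the admixed populations."""
    a, b = scenario.freq.admixture_beta
    return {
        pop: rng.beta(a, b, size=scenario.pop_size)
        for pop in scenario.pop_names
        if pop in ADMIXED
    }


def simulate_background_genotypes(
    scenario: SimulationScenario,
    n_snps: int,
    rng,
    admixture: Optional[dict] = None,
):
    """Generate the structured background genotype panel used for AGV.

    SNPs are independent (pre-pruned by construction).  Non-admixed
    individuals draw Binomial(2, f_pop); admixed individuals draw
    Binomial(2, a_i f_pop + (1-a_i) f_other_block) with individual-level
    admixture a_i.  Returns (GenotypeMatrix, population labels, admixture).
    """
    if admixture is None:
        admixture = draw_admixture(scenario, rng)
    n = scenario.n_total
    labels = scenario.labels()
    block_freqs, pop_freqs = _draw_hierarchical_freqs_batch(scenario, n_snps, rng)
    # float32: the panel exists only to estimate AGV, and at genome-wide-like
    # SNP counts the float64 copy would dominate memory
    dosage = np.empty((n, n_snps), dtype=np.float32)
    offset = 0
    for pop, anc in scenario.populations:
        sl = slice(offset, offset + scenario.pop_size)
        if pop in ADMIXED:
            a = admixture[pop][:, None]
            f_ind = a * pop_freqs[pop][None, :] + (1 - a) * (
                block_freqs[ADMIXED[pop]][None, :]
            )
        else:
            f_ind = np.broadcast_to(
                pop_freqs[pop][None, :], (scenario.pop_size, n_snps)
            )
        dosage[sl, :] = rng.binomial(2, f_ind)
        offset += scenario.pop_size
    samples = [f"{pop}_{i}" for pop in scenario.pop_names
               for i in range(scenario.pop_size)]
    variants = [
        VariantRecord(chrom="1", pos=j + 1, id=f"bg{j}", ref="A", alt="G")
        for j in range(n_snps)
    ]
    gm = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    return gm, labels, admixture


def _hwe_probs(f: float) -> np.ndarray:
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])


def case_genotype_probs(
    f: float, log_or: float, prevalence: Optional[float] = None
) -> np.ndarray:
    """Genotype distribution among cases.

    Rare-disease retrospective form: P(g | case) proportional to
    HWE(g) * exp(log_or * g).  When a prevalence is given, the logistic
    intercept alpha is solved so the population prevalence matches, and
    P(g | case) proportional to HWE(g) * expit(alpha + log_or * g).
    """
    hwe = _hwe_probs(f)
    g = np.arange(3)
    if prevalence is None:
        w = hwe * np.exp(log_or * g)
    else:
        alpha = _solve_prevalence_intercept(f, log_or, prevalence)
        w = hwe * expit(alpha + log_or * g)
    return w / w.sum()


def control_genotype_probs(
    f: float, log_or: float, prevalence: Optional[float] = None
) -> np.ndarray:
    """Genotype distribution among controls: HWE under the rare-disease
    approximation, or HWE(g)*(1 - P(case|g)) at exact prevalence."""
    hwe = _hwe_probs(f)
    if prevalence is None:
        return hwe
    alpha = _solve_prevalence_intercept(f, log_or, prevalence)
    w = hwe * (1.0 - expit(alpha + log_or * np.arange(3)))
    return w / w.sum()


def _solve_prevalence_intercept(f: float, log_or: float, prevalence: float) -> float:
    hwe = _hwe_probs(f)
    g = np.arange(3)

    def gap(alpha):
        return float(hwe @ expit(alpha + log_or * g)) - prevalence

    return brentq(gap, -30.0, 30.0)


def _draw_categorical(probs: np.ndarray, size: int, rng) -> np.ndarray:
    return np.searchsorted(np.cumsum(probs), rng.random(size)).astype(float)


def simulate_causal_replicate(scenario: SimulationScenario, rng):
    """Draw one causal-SNP replicate.

    The causal frequency follows the same Balding-Nichols hierarchy as the
    background; genotypes are sampled retrospectively per population given
    its case:control split and log-odds ratio.  Returns (dosage vector,
    phenotype vector, population labels); the phenotype vector is the
    scenario's fixed configuration.
    """
    _, pop_freqs = _draw_hierarchical_freqs(scenario, rng)
    y = scenario.phenotype()
    labels = scenario.labels()
    g = np.empty(scenario.n_total)
    offset = 0
    for pop in scenario.pop_names:
        f = pop_freqs[pop]
        beta = scenario.log_ors.get(pop, 0.0)
        nc = scenario.n_cases(pop)
        n0 = scenario.pop_size - nc
        if nc:
            g[offset : offset + nc] = _draw_categorical(
                case_genotype_probs(f, beta, scenario.prevalence), nc, rng
            )
        if n0:
            g[offset + nc : offset + scenario.pop_size] = _draw_categorical(
                control_genotype_probs(f, beta, scenario.prevalence), n0, rng
            )
        offset += scenario.pop_size
    return g, y, labels


# ---------------------------------------------------------------------------
# replicate engine

@dataclass
class Background:
    """Per-scenario fixtures computed once: background panel, multi-ethnic
    AGV, per-population AGV, and sample bookkeeping."""

    gm: GenotypeMatrix
    labels: np.ndarray
    agv: np.ndarray  # (n, K) multi-ethnic axes
    pop_axes: dict  # pop -> (pop_size, n_pop_agv) axes
    pop_slices: dict
    admixture: dict

    @classmethod
    def build(cls, scenario: SimulationScenario, rng) -> "Background":
        gm, labels, admixture = simulate_background_genotypes(
            scenario, scenario.n_background_snps, rng
        )
        agv = compute_agv_from_genotypes(gm, scenario.n_multiethnic_agv).axes
        pop_axes, pop_slices = {}, {}
        offset = 0
        for pop in scenario.pop_names:
            idx = np.arange(offset, offset + scenario.pop_size)
            pop_slices[pop] = idx
            pop_axes[pop] = compute_agv_from_genotypes(
                gm.subset(sample_idx=idx), scenario.n_pop_agv
            ).axes
            offset += scenario.pop_size
        return cls(
            gm=gm, labels=labels, agv=agv, pop_axes=pop_axes,
            pop_slices=pop_slices, admixture=admixture,
        )


@dataclass
class PowerTable:
    """Rejection proportions per analysis x threshold with Monte-Carlo SEs."""

    table: pd.DataFrame
    pvalues: dict  # analysis -> array of per-replicate P values
    scenario: SimulationScenario
    seed: int

    def to_tsv(self, path, sidecar: Optional[str] = None) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")
        if sidecar:
            prov = {
                "seed": int(self.seed),
                "model": self.scenario.model,
                "structure": self.scenario.structure,
                "effect_size": self.scenario.effect_size,
                "n_replicates": int(
                    len(next(iter(self.pvalues.values())))
                ),
                "n_background_snps": self.scenario.n_background_snps,
            }
            with open(sidecar, "w") as fh:
                json.dump(prov, fh, indent=2)


def estimate_power(p_values, threshold: float):
    """Fraction of P values strictly below ``threshold`` and its binomial
    Monte-Carlo SE; failed replicates (NaN) count as non-rejections."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("no P values")
    with np.errstate(invalid="ignore"):
        phat = float(np.mean(p < threshold))
    se = float(np.sqrt(phat * (1.0 - phat) / p.size))
    return phat, se


def run_replicates(
    scenario: SimulationScenario,
    analyses: Sequence[str] = ANALYSES,
    seed: int = 0,
    n_replicates: Optional[int] = None,
    background: Optional[Background] = None,
) -> PowerTable:
    """Run the replicate study for one scenario.

    Background genotypes and all AGV are computed once; each replicate
    draws a fresh causal SNP from its own seed substream, runs the
    requested analyses, and the per-threshold rejection proportions are
    aggregated.  Passing a prebuilt ``background`` lets several scenario
    cells share one cohort (the panel does not depend on the phenotype).
    """
    unknown = set(analyses) - set(ANALYSES)
    if unknown:
        raise ValidationError(f"unknown analyses: {sorted(unknown)}")
    R = int(n_replicates or scenario.n_replicates)
    children = np.random.SeedSequence(seed).spawn(R + 1)
    if background is None:
        background = Background.build(scenario, np.random.default_rng(children[0]))

    y = scenario.phenotype().astype(float)
    agv = background.agv
    n = len(y)
    ones = np.ones(n)

    need_glm = {"glm_agv", "het_interaction"} & set(analyses)
    need_meta = {"meta_fixed", "het_cochran_q"} & set(analyses)

    # null fits that do not involve the causal SNP are shared by replicates
    null_agv = (
        fit_logistic(y, np.column_stack([ones, agv]), check_rank=False)
        if need_glm
        else None
    )
    null_un = (
        fit_logistic(y, ones[:, None], check_rank=False)
        if "glm_unadjusted" in analyses
        else None
    )
    pop_nulls = {}
    if need_meta:
        for pop in scenario.pop_names:
            idx = background.pop_slices[pop]
            y_p = y[idx]
            if y_p.min() == y_p.max():
                pop_nulls[pop] = None  # single phenotype class: dropped
                continue
            Xp = np.column_stack([np.ones(len(idx)), background.pop_axes[pop]])
            pop_nulls[pop] = fit_logistic(y_p, Xp, check_rank=False)

    pvals = {a: np.full(R, np.nan) for a in analyses}
    for r in range(R):
        rng = np.random.default_rng(children[r + 1])
        g, _, _ = simulate_causal_replicate(scenario, rng)
        if g.min() == g.max():
            continue  # monomorphic draw: all analyses skip this replicate

        if need_glm:
            X = np.column_stack([ones, g, agv])
            start = np.insert(null_agv.params, 1, 0.0)
            fit = fit_logistic(y, X, start=start, check_rank=False)
            if fit.converged:
                if "glm_agv" in pvals:
                    _, pvals["glm_agv"][r] = lrt_pvalue(
                        fit.loglik, null_agv.loglik, 1
                    )
                if "het_interaction" in pvals:
                    Xh = np.column_stack([X, g * agv[:, 0], g * agv[:, 1]])
                    sh = np.concatenate([fit.params, [0.0, 0.0]])
                    fh = fit_logistic(y, Xh, start=sh, check_rank=False)
                    if fh.converged:
                        _, pvals["het_interaction"][r] = lrt_pvalue(
                            fh.loglik, fit.loglik, 2
                        )
        if "glm_unadjusted" in pvals:
            fit = fit_logistic(
                y, np.column_stack([ones, g]),
                start=np.insert(null_un.params, 1, 0.0), check_rank=False,
            )
            if fit.converged:
                _, pvals["glm_unadjusted"][r] = lrt_pvalue(
                    fit.loglik, null_un.loglik, 1
                )
        if need_meta:
            betas, ses = [], []
            for pop in scenario.pop_names:
                nullp = pop_nulls[pop]
                if nullp is None:
                    continue
                idx = background.pop_slices[pop]
                g_p = g[idx]
                if g_p.min() == g_p.max():
                    continue
                Xp = np.column_stack(
                    [np.ones(len(idx)), g_p, background.pop_axes[pop]]
                )
                fp = fit_logistic(
                    y[idx], Xp, start=np.insert(nullp.params, 1, 0.0),
                    check_rank=False,
                )
                if fp.converged:
                    betas.append(float(fp.params[1]))
                    ses.append(fp.se(1))
            if betas:
                if "meta_fixed" in pvals:
                    pvals["meta_fixed"][r] = ivw_meta(betas, ses).p_value
                if "het_cochran_q" in pvals and len(betas) > 1:
                    _, _, pvals["het_cochran_q"][r] = cochran_q(betas, ses)

    rows = []
    for a in analyses:
        for t in scenario.thresholds:
            power, se = estimate_power(pvals[a], t)
            rows.append(
                {
                    "analysis": a, "model": scenario.model,
                    "structure": scenario.structure,
                    "effect_size": scenario.effect_size, "threshold": t,
                    "power": power, "mc_se": se, "n_replicates": R,
                }
            )
    return PowerTable(
        table=pd.DataFrame(rows), pvalues=pvals, scenario=scenario, seed=seed
    )


def run_grid(
    models: Sequence[str],
    structures: Sequence[str],
    effect_sizes: Sequence[float],
    analyses: Sequence[str] = ANALYSES,
    seed: int = 0,
    n_replicates: int = 500,
    background: Optional[Background] = None,
    **scenario_overrides,
) -> dict:
    """Run a model x structure x effect-size grid of scenarios.

    The background cohort is built once (it is phenotype-free) and shared
    by every cell.  Returns ``{(model, structure, effect): PowerTable}``.
    """
    root = np.random.SeedSequence(seed)
    bg_seed, cell_root = root.spawn(2)
    if background is None:
        template = make_scenario(
            models[0], structures[0], 0.0, **scenario_overrides
        )
        background = Background.build(template, np.random.default_rng(bg_seed))
    cells = [
        (m, s, e) for m in models for s in structures for e in effect_sizes
    ]
    out = {}
    for cell_seed, (m, s, e) in zip(cell_root.spawn(len(cells)), cells):
        scenario = make_scenario(m, s, e, **scenario_overrides)
        out[(m, s, e)] = run_replicates(
            scenario, analyses=analyses,
            seed=int(cell_seed.generate_state(1)[0] % (2**31)),
            n_replicates=n_replicates, background=background,
        )
    return out
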