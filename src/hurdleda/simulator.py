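"""Synthetic microbial communities with known ground-truth associations.

Features follow zero-inflated log-normal null distributions on the
absolute scale.  Abundance (log-linear) and prevalence (logistic)
associations are imposed on that absolute scale, after which the community
is renormalized and sequencing is emulated by multinomial read sampling at
a log-normally distributed depth — so the data handed to the models are
compositional counts while the truth is absolute, exactly the regime the
median comparison targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .io_formats import AssociationRecord, CovariateRole, FeatureTable, MetadataTable
from .preprocessing import AbsoluteScalingInfo
from .results import significance_filter

logger = logging.getLogger("hurdleda")

SPIKE_FEATURE = "spike_ref"

#: sentinel log-odds coefficient recorded for structural-zero truths
STRUCTURAL_ZERO_COEF = -10.0


@dataclass
class NullTemplate:
    """Per-feature null parameters: prevalence pi, log2-mean mu, log2-sd
    sigma of the zero-inflated log-normal absolute abundances."""

    prevalence: np.ndarray
    log2_mean: np.ndarray
    log2_sd: np.ndarray
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_ids:
            self.feature_ids = [f"F{i+1:04d}" for i in range(len(self.prevalence))]
        if np.any(self.log2_sd <= 0):
            raise ValueError("all sigma_i must be positive")
        if np.any((self.prevalence <= 0) | (self.prevalence > 1)):
            raise ValueError("all pi_i must lie in (0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.prevalence)

    @classmethod
    def draw(cls, n_features: int, seed: int | np.random.Generator = 0) -> "NullTemplate":
        """Draw a template from the default hyper-distributions:
        pi ~ Beta(0.5, 2) (median prevalence around 0.1, i.e. a sparse
        community), mu ~ Normal(0, 2), sigma ~ |Normal(0,1)| + 0.5."""
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        pi = np.clip(rng.beta(0.5, 2.0, size=n_features), 1e-4, 1.0)
        mu = rng.normal(0.0, 2.0, size=n_features)
        sd = np.abs(rng.normal(0.0, 1.0, size=n_features)) + 0.5
        return cls(prevalence=pi, log2_mean=mu, log2_sd=sd)

    @classmethod
    def read(cls, path) -> "NullTemplate":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            prevalence=df["prevalence"].to_numpy(float),
            log2_mean=df["log2_mean"].to_numpy(float),
            log2_sd=df["log2_sd"].to_numpy(float),
            feature_ids=list(df.index.astype(str)),
        )

    def write(self, path) -> None:
        pd.DataFrame(
            {
                "prevalence": self.prevalence,
                "log2_mean": self.log2_mean,
                "log2_sd": self.log2_sd,
            },
            index=pd.Index(self.feature_ids, name="feature"),
        ).to_csv(path, sep="\t")


@dataclass
class SimulatedDataset:
    counts: FeatureTable
    metadata: MetadataTable
    truth: pd.DataFrame  # columns: feature, covariate, type, coefficient
    spike_in: Optional[AbsoluteScalingInfo] = None
    absolute: Optional[FeatureTable] = None
    seed: Optional[int] = None


def simulate_metadata(
    n: int,
    g: int,
    n_subjects: Optional[int] = None,
    seed: int | np.random.Generator = 0,
) -> MetadataTable:
    """Synthetic covariates: g columns from a standard multivariate normal,
    the first floor(g/2) dichotomized at 0 (so binary columns have marginal
    prevalence 1/2).  With ``n_subjects``, covariates are drawn once per
    subject and shared within subject, and a ``subject`` random-grouping
    column is added."""
    if g < 1:
        raise ValueError("need at least one covariate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = [f"meta_{j+1}" for j in range(g)]
    n_binary = g // 2
    if n_subjects is None:
        Z = rng.multivariate_normal(np.zeros(g), np.eye(g), size=n)
        df = pd.DataFrame(Z, columns=names, index=[f"S{i+1:05d}" for i in range(n)])
    else:
        Zs = rng.multivariate_normal(np.zeros(g), np.eye(g), size=n_subjects)
        assignment = np.repeat(np.arange(n_subjects), int(np.ceil(n / n_subjects)))[:n]
        df = pd.DataFrame(
            Zs[assignment], columns=names, index=[f"S{i+1:05d}" for i in range(n)]
        )
        df["subject"] = [f"subj_{a+1:04d}" for a in assignment]
    for j in range(n_binary):
        df[names[j]] = (df[names[j]] > 0).astype(float)
    roles = {name: CovariateRole("continuous") for name in names}
    if n_subjects is not None:
        roles["subject"] = CovariateRole("random_grouping")
    return MetadataTable(df, roles=roles)


def simulate_truth(
    feature_ids: list[str],
    covariates: list[str],
    spiked_fraction: float = 0.10,
    effect_range: tuple[float, float] = (2.5, 5.0),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Spike a fraction of feature-by-covariate pairs: half abundance, half
    prevalence; half positive, half negative; magnitudes U(lo, hi)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs = [(f, c) for f in feature_ids for c in covariates]
    k = int(round(spiked_fraction * len(pairs)))
    chosen = rng.choice(len(pairs), size=k, replace=False)
    types = np.where(np.arange(k) % 2 == 0, "abundance", "prevalence")
    rng.shuffle(types)
    signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    rng.shuffle(signs)
    mags = rng.uniform(effect_range[0], effect_range[1], size=k)
    rows = [
        {
            "feature": pairs[i][0],
            "covariate": pairs[i][1],
            "type": types[j],
            "coefficient": signs[j] * mags[j],
        }
        for j, i in enumerate(chosen)
    ]
    return pd.DataFrame(rows, columns=["feature", "covariate", "type", "coefficient"])


def simulate_community(
    template: NullTemplate,
    md: MetadataTable,
    truth: pd.DataFrame,
    depth_mean: float = 50_000.0,
    depth_log_sd: float = 0.5,
    spike_in: bool = False,
    subject_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> SimulatedDataset:
    """Generate counts with the given associations imposed on the absolute
    scale.

    Per sample: feature presence is Bernoulli on the logit scale
    (logit(pi_i) plus any prevalence spikes times the covariates); present
    features draw log2 abundance Normal(mu_i + abundance spikes x, sigma_i^2)
    (plus a per-subject random intercept, sd ``subject_sd``, when the
    metadata carries a ``subject`` column).  A spike-in reference feature,
    when requested, is added at a uniform 1-10% of each sample's total
    absolute abundance and its absolute value recorded.  Reads are then
    drawn multinomially at a log-normal depth with the given mean.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    unknown = set(truth["feature"]) - set(template.feature_ids)
    if unknown:
        raise ValueError(f"truth features not in template: {sorted(unknown)[:5]}")
    n = len(md.data)
    m = template.n_features
    # only numeric covariates can carry spiked effects (ordered covariates
    # are spiked through their thermometer-encoded numeric columns)
    fixed_covs = [
        c
        for c in md.fixed_effect_covariates()
        if pd.api.types.is_numeric_dtype(md.data[c])
    ]
    non_numeric = set(truth["covariate"]) - set(fixed_covs)
    if non_numeric:
        raise ValueError(
            f"truth references non-numeric covariates: {sorted(non_numeric)}"
        )
    Xc = md.data[fixed_covs].to_numpy(float)

    beta_ab = np.zeros((len(fixed_covs), m))
    beta_pr = np.zeros((len(fixed_covs), m))
    f_idx = {f: i for i, f in enumerate(template.feature_ids)}
    c_idx = {c: j for j, c in enumerate(fixed_covs)}
    for _, row in truth.iterrows():
        tgt = beta_ab if row["type"] == "abundance" else beta_pr
        tgt[c_idx[row["covariate"]], f_idx[row["feature"]]] = row["coefficient"]

    eta_prev = logit(np.clip(template.prevalence, 1e-12, 1 - 1e-12))[None, :] + Xc @ beta_pr
    mean_ab = template.log2_mean[None, :] + Xc @ beta_ab

    subject_effect = np.zeros(n)
    if "subject" in md.data.columns:
        codes, uniq = pd.factorize(md.data["subject"])
        subject_effect = rng.normal(0.0, subject_sd, size=len(uniq))[codes]

    prob = expit(eta_prev)
    absolute = np.zeros((n, m))
    for k in range(n):
        for attempt in range(100):
            present = rng.random(m) < prob[k]
            if present.any():
                break
            logger.info("sample %d: all features absent, redrawing (attempt %d)", k, attempt + 1)
        else:
            present[rng.integers(m)] = True
        log2_ab = rng.normal(mean_ab[k], template.log2_sd) + subject_effect[k]
        absolute[k] = np.where(present, np.exp2(log2_ab), 0.0)

    sample_ids = list(md.data.index)
    feature_ids = list(template.feature_ids)
    spike_info = None
    if spike_in:
        totals = absolute.sum(axis=1)
        ref_abs = rng.uniform(0.01, 0.10, size=n) * totals
        absolute = np.hstack([absolute, ref_abs[:, None]])
        feature_ids = feature_ids + [SPIKE_FEATURE]
        spike_info = AbsoluteScalingInfo(
            mode="spike_in",
            reference_feature=SPIKE_FEATURE,
            reference_abs=pd.Series(ref_abs, index=sample_ids),
        )

    rel = absolute / absolute.sum(axis=1, keepdims=True)
    log_mu = np.log(depth_mean) - depth_log_sd**2 / 2.0
    depths = np.maximum(1, np.round(rng.lognormal(log_mu, depth_log_sd, size=n))).astype(int)
    counts = np.vstack([rng.multinomial(depths[k], rel[k]) for k in range(n)])

    counts_ft = FeatureTable(
        pd.DataFrame(counts.astype(float), index=sample_ids, columns=feature_ids),
        scale="counts",
    )
    abs_ft = FeatureTable(
        pd.DataFrame(absolute, index=sample_ids, columns=feature_ids), scale="absolute"
    )
    return SimulatedDataset(
        counts=counts_ft,
        metadata=md,
        truth=truth.reset_index(drop=True),
        spike_in=spike_info,
        absolute=abs_ft,
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_ordered_covariate(
    n: int,
    levels: int,
    total_effect: float,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.Series, np.ndarray]:
    """An ordered covariate plus its per-step effect coefficients.

    The total effect (difference between the first and last level) is
    divided among the L-1 consecutive steps by a Dirichlet(1,...,1) draw;
    then, left to right, each step is zeroed with probability 1/2 and its
    mass carried to the next step (the last step keeps whatever it
    receives), producing effects that can concentrate at thresholds.
    Observed levels are sampled uniformly.
    """
    if levels < 3:
        raise ValueError("ordered covariates need at least 3 levels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    steps = total_effect * rng.dirichlet(np.ones(levels - 1))
    for t in range(levels - 2):
        if rng.random() < 0.5:
            steps[t + 1] += steps[t]
            steps[t] = 0.0
    names = [f"lev{j+1}" for j in range(levels)]
    column = pd.Series(
        rng.choice(names, size=n), index=[f"S{i+1:05d}" for i in range(n)], name="ordered_1"
    )
    return column, steps


def simulate_structural_zeros(
    template: NullTemplate,
    n_per_group: int,
    frac_structural: float = 0.20,
    frac_affected: float = 0.10,
    effect_range: tuple[float, float] = (2.5, 5.0),
    depth_mean: float = 50_000.0,
    depth_log_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> SimulatedDataset:
    """Two-group design with multiplicative abundance effects and structural
    zeros.

    A fraction of features has its group-2 mean absolute abundance
    multiplied by U(2.5, 5); a random ``frac_structural`` of features is
    additionally set to zero in every group-2 sample (structural zeros, a
    pure prevalence effect recorded with a sentinel coefficient).  Reads
    are subsampled at log-normal depths with the given mean.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = template.n_features
    n = 2 * n_per_group
    group = np.array([0] * n_per_group + [1] * n_per_group)
    sample_ids = [f"S{i+1:05d}" for i in range(n)]
    md = MetadataTable(
        pd.DataFrame({"group": group.astype(float)}, index=sample_ids),
        roles={"group": CovariateRole("continuous")},
    )

    n_affected = int(round(frac_affected * m))
    affected = rng.choice(m, size=n_affected, replace=False)
    multipliers = rng.uniform(effect_range[0], effect_range[1], size=n_affected)
    n_struct = int(round(frac_structural * m))
    structural = rng.choice(m, size=n_struct, replace=False)

    log2_shift = np.zeros(m)
    log2_shift[affected] = np.log2(multipliers)

    absolute = np.zeros((n, m))
    for k in range(n):
        present = rng.random(m) < template.prevalence
        mean_k = template.log2_mean + group[k] * log2_shift
        log2_ab = rng.normal(mean_k, template.log2_sd)
        absolute[k] = np.where(present, np.exp2(log2_ab), 0.0)
    absolute[np.ix_(group == 1, structural)] = 0.0
    # guard: no all-zero samples
    for k in range(n):
        if absolute[k].sum() == 0:
            keep = rng.integers(m)
            while keep in structural and group[k] == 1:
                keep = rng.integers(m)
            absolute[k, keep] = np.exp2(rng.normal(template.log2_mean[keep], template.log2_sd[keep]))

    rel = absolute / absolute.sum(axis=1, keepdims=True)
    log_mu = np.log(depth_mean) - depth_log_sd**2 / 2.0
    depths = np.maximum(1, np.round(rng.lognormal(log_mu, depth_log_sd, size=n))).astype(int)
    counts = np.vstack([rng.multinomial(depths[k], rel[k]) for k in range(n)])

    rows = [
        {
            "feature": template.feature_ids[i],
            "covariate": "group",
            "type": "abundance",
            "coefficient": float(np.log2(u)),
        }
        for i, u in zip(affected, multipliers)
        if i not in set(structural)
    ]
    rows += [
        {
            "feature": template.feature_ids[i],
            "covariate": "group",
            "type": "prevalence",
            "coefficient": STRUCTURAL_ZERO_COEF,
        }
        for i in structural
    ]
    truth = pd.DataFrame(rows, columns=["feature", "covariate", "type", "coefficient"])
    return SimulatedDataset(
        counts=FeatureTable(
            pd.DataFrame(counts.astype(float), index=sample_ids, columns=template.feature_ids),
            scale="counts",
        ),
        metadata=md,
        truth=truth,
        absolute=FeatureTable(
            pd.DataFrame(absolute, index=sample_ids, columns=template.feature_ids),
            scale="absolute",
        ),
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass
class BenchmarkMetrics:
    precision: Optional[float]
    recall: float
    f1: Optional[float]
    relative_shrinkage_error: Optional[float]
    spearman: Optional[float]
    n_discoveries: int
    n_true: int


def score_run(
    records: list[AssociationRecord],
    truth: pd.DataFrame,
    q_threshold: float = 0.1,
    match_type: bool = False,
    effect_threshold: float = 0.0,
) -> BenchmarkMetrics:
    """Score a fitted run against the ground truth.

    A discovery is an error-free record passing the q threshold — the joint
    q-value when ``match_type`` is off (overall association, deduplicated to
    feature-covariate pairs), the per-half individual q-value when it is on
    (so the claimed type is the model half that reached significance).  A
    discovery is correct if its (feature, covariate) pair — and, with
    ``match_type``, its association type — appears in the truth table.

    Also reports the relative shrinkage error, mean over type-matched true
    discoveries of (|fit| - |true|)/|true|, and the Spearman correlation
    between fitted and true abundance coefficients per covariate, averaged
    over covariates.
    """
    passing = significance_filter(
        records,
        q_threshold=q_threshold,
        effect_threshold=effect_threshold,
        use_joint=not match_type,
    )
    if match_type:
        discoveries = {(r.feature, r.metadata, r.model) for r in passing}
        truth_keys = {(t.feature, t.covariate, t.type) for t in truth.itertuples()}
    else:
        discoveries = {(r.feature, r.metadata) for r in passing}
        truth_keys = {(t.feature, t.covariate) for t in truth.itertuples()}
    correct = discoveries & truth_keys
    n_disc, n_true = len(discoveries), len(truth_keys)
    precision = len(correct) / n_disc if n_disc else None
    recall = len(correct) / n_true if n_true else 0.0
    f1 = None
    if precision is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)

    truth_coef = {(t.feature, t.covariate, t.type): t.coefficient for t in truth.itertuples()}
    shrink = []
    for r in passing:
        key = (r.feature, r.metadata, r.model)
        if key in truth_coef and r.coef is not None and np.isfinite(truth_coef[key]):
            true_b = truth_coef[key]
            shrink.append((abs(r.coef) - abs(true_b)) / abs(true_b))
    shrinkage = float(np.mean(shrink)) if shrink else None

    fit_ab = {
        (r.feature, r.metadata): r.coef
        for r in records
        if r.model == "abundance" and r.error is None and r.coef is not None
    }
    covariates = sorted({t.covariate for t in truth.itertuples()}) or sorted(
        {k[1] for k in fit_ab}
    )
    features = sorted({r.feature for r in records})
    cors = []
    for cov in covariates:
        fit_vec, true_vec = [], []
        for f in features:
            if (f, cov) in fit_ab:
                fit_vec.append(fit_ab[(f, cov)])
                true_vec.append(truth_coef.get((f, cov, "abundance"), 0.0))
        if len(fit_vec) >= 3 and np.std(true_vec) > 0:
            rho = stats.spearmanr(fit_vec, true_vec).statistic
            if np.isfinite(rho):
                cors.append(rho)
    spearman = float(np.mean(cors)) if cors else None
    return BenchmarkMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        relative_shrinkage_error=shrinkage,
        spearman=spearman,
        n_discoveries=n_disc,
        n_true=n_true,
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write counts/metadata/truth (and the spike-in vector) as TSV files."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    paths["counts"] = os.path.join(out_dir, "counts.tsv")
    ds.counts.data.astype(int).to_csv(paths["counts"], sep="\t", index_label="sample")
    paths["metadata"] = os.path.join(out_dir, "metadata.tsv")
    ds.metadata.data.to_csv(paths["metadata"], sep="\t", index_label="sample", na_rep="NA")
    paths["truth"] = os.path.join(out_dir, "truth.tsv")
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    if ds.spike_in is not None:
        paths["spike_in"] = os.path.join(out_dir, "spike_in.tsv")
        ds.spike_in.reference_abs.rename("abundance").to_csv(
            paths["spike_in"], sep="\t", index_label="sample"
        )
    return paths
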