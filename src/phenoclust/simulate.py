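"""Seeded generators for screen count tables and methylation beta matrices.

Both generators plant a known ground truth (gene effect classes for the
screen, sample groups and informative probes for the methylation cohort) so
that every downstream stage of the two pipelines can be verified against the
configuration that produced its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

SCREEN_CLASSES = ("essential", "fitness_suppressor", "resistance", "sensitizer", "neutral")
FLAG_KEYS = ("sex_chrom", "snp_overlap", "multimap", "detection_fail")

_DNA = np.array(list("ACGT"))


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator.

    Attributes
    ----------
    construct_classes
        Screen only: construct_id -> effect class (one of ``SCREEN_CLASSES``
        or ``"ntc"`` for non-targeting controls).
    sample_groups
        Methylation only: sample_id -> group label.
    probe_groups
        Methylation only: probe_id -> group label whose samples are shifted
        on that probe, or ``None`` for uninformative probes.
    """

    construct_classes: pd.Series | None = None
    sample_groups: pd.Series | None = None
    probe_groups: pd.Series | None = None


@dataclass
class ScreenSimConfig:
    """Configuration for the pooled dual-sgRNA screen generator.

    The default scale (2000 genes, 100 NTC pairs) is a desk-scale stand-in
    for the genome-wide library (23,483 genes, 1137 NTC pairs), available
    via :meth:`full_scale`.  Growth effects are log2 fold changes per
    population doubling: ``gamma`` acts in every arm, ``rho`` only in the
    drug arm.
    """

    n_genes: int = 2000
    n_ntc_pairs: int = 100
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "essential": 0.10,
            "fitness_suppressor": 0.02,
            "resistance": 0.01,
            "sensitizer": 0.01,
            "neutral": 0.86,
        }
    )
    gamma_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "essential": -0.3,
            "fitness_suppressor": 0.2,
            "resistance": 0.0,
            "sensitizer": 0.0,
            "neutral": 0.0,
        }
    )
    rho_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "essential": 0.0,
            "fitness_suppressor": 0.0,
            "resistance": 0.5,
            "sensitizer": -0.5,
            "neutral": 0.0,
        }
    )
    doublings: Mapping[str, float] = field(
        default_factory=lambda: {"vehicle": 8.0, "drug": 6.0}
    )
    n_replicates: int = 3
    depth_per_construct: float = 500.0
    overdispersion: float = 1000.0
    abundance_sigma: float = 0.5
    seed: int = 0

    @classmethod
    def full_scale(cls, **overrides) -> "ScreenSimConfig":
        """Preset at the size of the genome-wide library."""
        params = dict(n_genes=23483, n_ntc_pairs=1137)
        params.update(overrides)
        return cls(**params)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be a positive integer")
        if self.n_ntc_pairs <= 0:
            raise ConfigError("n_ntc_pairs must be a positive integer")
        missing = set(SCREEN_CLASSES) - set(self.class_fractions)
        if missing:
            raise ConfigError(f"class_fractions missing classes: {sorted(missing)}")
        total = sum(self.class_fractions[c] for c in SCREEN_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_fractions must sum to 1 (got {total!r})")
        if any(self.class_fractions[c] < 0 for c in SCREEN_CLASSES):
            raise ConfigError("class_fractions must be non-negative")
        for arm, d in self.doublings.items():
            if d <= 0:
                raise ConfigError(f"doublings[{arm!r}] must be > 0")
        if self.depth_per_construct <= 0:
            raise ConfigError("depth_per_construct must be > 0")
        if self.overdispersion <= 0:
            raise ConfigError("overdispersion must be > 0")
        if self.abundance_sigma < 0:
            raise ConfigError("abundance_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("class_fractions", "gamma_effects", "rho_effects", "doublings"):
            d[key] = dict(d[key])
        return d


@dataclass
class MethSimConfig:
    """Configuration for the methylation beta-matrix generator.

    The default ``group_sizes`` (25, 8, 86; 119 samples) mirror the relative
    sizes of the three tumor groups the clustering pipeline is meant to
    recover.  Informative probes for a group are separated from the other
    groups by ``beta_shift`` in beta units; uninformative probes draw their
    level from a bimodal two-component Beta mixture, reproducing the typical
    bimodality of methylation fractions.
    """

    group_sizes: Sequence[int] = (25, 8, 86)
    n_probes: int = 20000
    n_informative_per_group: int = 500
    beta_shift: float = 0.4
    background_mixture: tuple = ((2.0, 10.0), (10.0, 2.0), 0.5)
    sample_noise_sd: float = 0.05
    n_flagged: Mapping[str, int] = field(
        default_factory=lambda: {
            "sex_chrom": 1000,
            "snp_overlap": 500,
            "multimap": 500,
            "detection_fail": 200,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if len(self.group_sizes) == 0:
            raise ConfigError("group_sizes must be non-empty")
        if any(int(s) <= 0 for s in self.group_sizes):
            raise ConfigError("group_sizes must all be positive")
        if any(int(s) == 1 for s in self.group_sizes):
            logger.warning("group_sizes contains a singleton group; silhouette "
                           "diagnostics may be unstable")
        if not (0 < self.beta_shift <= 1):
            raise ConfigError("beta_shift must lie in (0, 1]")
        (a1, b1), (a2, b2), mix = self.background_mixture
        if min(a1, b1, a2, b2) <= 0:
            raise ConfigError("background_mixture Beta parameters must be > 0")
        if not (0 <= mix <= 1):
            raise ConfigError("background_mixture mixing weight must lie in [0, 1]")
        if self.sample_noise_sd < 0:
            raise ConfigError("sample_noise_sd must be >= 0")
        if self.n_probes <= 0:
            raise ConfigError("n_probes must be positive")
        if self.n_informative_per_group < 0:
            raise ConfigError("n_informative_per_group must be >= 0")
        unknown = set(self.n_flagged) - set(FLAG_KEYS)
        if unknown:
            raise ConfigError(f"n_flagged has unknown keys: {sorted(unknown)}")
        if any(v < 0 for v in self.n_flagged.values()):
            raise ConfigError("n_flagged counts must be >= 0")
        reserved = (len(self.group_sizes) * self.n_informative_per_group
                    + sum(self.n_flagged.values()))
        if reserved > self.n_probes:
            raise ConfigError(
                f"n_probes={self.n_probes} too small for "
                f"{reserved} informative + flagged probes"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = [int(s) for s in self.group_sizes]
        d["n_flagged"] = dict(d["n_flagged"])
        d["background_mixture"] = [list(self.background_mixture[0]),
                                   list(self.background_mixture[1]),
                                   self.background_mixture[2]]
        return d


def _random_protospacers(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    """Draw ``n`` distinct random DNA sequences."""
    seqs: dict[str, None] = {}
    while len(seqs) < n:
        block = rng.integers(0, 4, size=(n - len(seqs), length))
        for row in block:
            seqs.setdefault("".join(_DNA[row]), None)
    return list(seqs)[:n]


def _class_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Integer class sizes by largest-remainder apportionment."""
    raw = {c: fractions[c] * n for c in SCREEN_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    # hand leftovers to the largest fractional remainders (ties: class order)
    order = sorted(SCREEN_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def simulate_screen(config: ScreenSimConfig):
    """Simulate a dual-condition pooled CRISPRi screen.

    Returns ``(library, samples, counts, truth)``: the construct registry,
    the sample sheet (one T0 baseline, ``n_replicates`` T10 replicates per
    arm), the construct x sample count matrix, and the planted truth.

    The generative model: T0 relative abundances are log-normal; the
    expected T10 abundance of construct *i* in an arm with ``D`` doublings is
    proportional to ``a_i * 2**(D * (gamma_i + rho_i * [drug arm]))``; each
    sample's counts are Dirichlet-multinomial with total depth
    ``n_constructs * depth_per_construct`` and per-construct concentration
    ``overdispersion`` on average, giving mildly super-Poisson counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    counts_by_class = _class_counts(config.class_fractions, config.n_genes)
    classes = np.concatenate(
        [np.repeat(c, counts_by_class[c]) for c in SCREEN_CLASSES]
    )
    classes = classes[rng.permutation(config.n_genes)]

    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    construct_ids = [f"{g}_sg" for g in genes] + [
        f"NTC{i:04d}" for i in range(config.n_ntc_pairs)
    ]
    n_constructs = len(construct_ids)
    gene_col = genes + ["NTC"] * config.n_ntc_pairs
    is_ntc = np.array([False] * config.n_genes + [True] * config.n_ntc_pairs)

    protos = _random_protospacers(rng, 2 * n_constructs)
    library = pd.DataFrame(
        {
            "construct_id": construct_ids,
            "gene": gene_col,
            "protospacer_a": protos[:n_constructs],
            "protospacer_b": protos[n_constructs:],
            "is_ntc": is_ntc,
        }
    ).set_index("construct_id")

    class_per_construct = np.concatenate([classes, np.repeat("ntc", config.n_ntc_pairs)])
    gamma = np.array(
        [config.gamma_effects.get(c, 0.0) for c in class_per_construct]
    )
    rho = np.array([config.rho_effects.get(c, 0.0) for c in class_per_construct])

    rows = [("T0", "baseline", "T0", 1)]
    for arm in ("vehicle", "drug"):
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{arm}_T10_r{r}", arm, "T10", r))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "arm", "timepoint", "replicate"]
    ).set_index("sample_id")

    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n_constructs)
    total_depth = int(round(n_constructs * config.depth_per_construct))

    count_cols = {}
    for sample_id, meta in samples.iterrows():
        if meta["timepoint"] == "T0":
            weight = np.ones(n_constructs)
        else:
            d = config.doublings[meta["arm"]]
            effect = gamma + rho * (meta["arm"] == "drug")
            weight = np.exp2(d * effect)
        p = abundance * weight
        p = p / p.sum()
        alpha = config.overdispersion * n_constructs * p
        q = rng.dirichlet(alpha)
        count_cols[sample_id] = rng.multinomial(total_depth, q)

    counts = pd.DataFrame(count_cols, index=pd.Index(construct_ids, name="construct_id"))
    truth = PlantedTruth(
        construct_classes=pd.Series(
            class_per_construct, index=counts.index, name="class"
        )
    )
    logger.info(
        "simulated screen: %d constructs (%d NTC), depth %d per sample",
        n_constructs, config.n_ntc_pairs, total_depth,
    )
    return library, samples, counts, truth


def simulate_methylation(config: MethSimConfig):
    """Simulate a methylation beta matrix with planted sample groups.

    Returns ``(beta, annotation, detection_p, truth)``.  Informative probes
    of group *g* separate that group's samples from all others by
    ``beta_shift`` (shift directed toward the interior of [0, 1]); all
    per-sample noise is Gaussian on the logit scale, keeping values inside
    (0, 1) and preserving the bimodal marginal distribution.  Flagged probe
    sets (sex chromosomes, SNP overlap, multi-mapping, detection failure)
    are mutually disjoint and disjoint from informative probes, so the
    filtering stage removes exactly their total.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    group_sizes = [int(s) for s in config.group_sizes]
    n_samples = sum(group_sizes)
    n_groups = len(group_sizes)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    group_labels = np.concatenate(
        [np.repeat(f"group{g + 1}", sz) for g, sz in enumerate(group_sizes)]
    )

    probe_ids = np.array([f"cg{i:08d}" for i in range(config.n_probes)])

    # reserve disjoint probe index blocks for informative + flagged sets
    n_inf_total = n_groups * config.n_informative_per_group
    n_reserved = n_inf_total + sum(config.n_flagged.get(k, 0) for k in FLAG_KEYS)
    reserved = rng.choice(config.n_probes, size=n_reserved, replace=False)
    pos = 0
    informative_idx = {}
    for g in range(n_groups):
        informative_idx[g] = reserved[pos:pos + config.n_informative_per_group]
        pos += config.n_informative_per_group
    flag_idx = {}
    for key in FLAG_KEYS:
        k = config.n_flagged.get(key, 0)
        flag_idx[key] = reserved[pos:pos + k]
        pos += k

    (a1, b1), (a2, b2), mix = config.background_mixture
    use_first = rng.random(config.n_probes) < mix
    base = np.where(
        use_first,
        rng.beta(a1, b1, size=config.n_probes),
        rng.beta(a2, b2, size=config.n_probes),
    )
    base = np.clip(base, 1e-3, 1 - 1e-3)

    # probe x sample matrix of planted means
    means = np.tile(base[:, None], (1, n_samples))
    for g in range(n_groups):
        idx = informative_idx[g]
        shift_up = base[idx] <= 0.5
        target = np.where(
            shift_up, base[idx] + config.beta_shift, base[idx] - config.beta_shift
        )
        target = np.clip(target, 1e-3, 1 - 1e-3)
        cols = group_labels == f"group{g + 1}"
        means[np.ix_(idx, cols)] = target[:, None]

    noise = rng.normal(0.0, config.sample_noise_sd, size=means.shape)
    beta_values = expit(logit(means) + noise)
    beta = pd.DataFrame(beta_values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sample_ids)

    chrom = np.array(
        [f"chr{c}" for c in rng.integers(1, 23, size=config.n_probes)], dtype=object
    )
    sex = flag_idx["sex_chrom"]
    half = len(sex) // 2
    chrom[sex[:half]] = "chrX"
    chrom[sex[half:]] = "chrY"
    snp = np.zeros(config.n_probes, dtype=bool)
    snp[flag_idx["snp_overlap"]] = True
    multi = np.zeros(config.n_probes, dtype=bool)
    multi[flag_idx["multimap"]] = True
    annotation = pd.DataFrame(
        {"chrom": chrom, "snp_overlap": snp, "multimap": multi},
        index=beta.index,
    )

    detp_values = rng.uniform(0.0, 0.049, size=means.shape)
    for i in flag_idx["detection_fail"]:
        n_fail = int(rng.integers(1, min(4, n_samples + 1)))
        cols = rng.choice(n_samples, size=n_fail, replace=False)
        detp_values[i, cols] = rng.uniform(0.05, 0.6, size=n_fail)
    detection_p = pd.DataFrame(detp_values, index=beta.index, columns=sample_ids)

    probe_groups = pd.Series(None, index=beta.index, dtype=object, name="group")
    for g in range(n_groups):
        probe_groups.iloc[informative_idx[g]] = f"group{g + 1}"

    truth = PlantedTruth(
        sample_groups=pd.Series(group_labels, index=sample_ids, name="group"),
        probe_groups=probe_groups,
    )
    logger.info(
        "simulated methylation cohort: %d probes x %d samples in %d groups",
        config.n_probes, n_samples, n_groups,
    )
    return beta, annotation, detection_p, truth
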