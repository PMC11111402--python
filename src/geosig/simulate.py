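"""Synthetic multi-country cohorts with planted ground truth.

Every pipeline stage is testable without any genome or controlled-access
download: the generator plants column-stochastic signature profiles, draws
per-sample signature sets from per-country prevalences, burdens from
log-normal distributions (the ubiquitous flat signature's mean burden
scales linearly with the country's age-standardized incidence rate), and
materializes channel counts as mutation records whose embedded contexts
classify back to exactly the intended channel (inverse classification).
Channel counts are multinomial conditional on the planted totals, so
ground-truth exposures are conserved exactly and any recovery error is
attributable to the pipeline, not the generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogue import MutationRecord
from .decomposition import SignatureMatrix, cosine_similarity
from .schemas import ChannelSchema, get_schema

# units used to realize repeat/microhomology indel channels; no T so that a
# T-pad never extends a run or a homology tract, and no unit starts/ends with T
_UNITS = {2: "AC", 3: "ACG", 4: "ACCG", 5: "ACCGG", 6: "ACCGGC"}
_STRAND_NAME = {"T": "transcribed", "U": "untranscribed", "N": "unknown"}


def records_for_channel(
    schema: ChannelSchema | str,
    label: str,
    sample_id: str,
    count: int = 1,
    chrom: str = "1",
    start_pos: int = 1000,
) -> list[MutationRecord]:
    """Mutation records that classify to exactly the given channel.

    This is a right inverse of classification: for every channel of every
    schema, ``classify(records_for_channel(schema, ch)[i]) == ch``.
    Contexts are minimal synthetic strings; positions are bookkeeping only.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    if label not in schema.index:
        raise KeyError(f"{label!r} is not a channel of {schema.name}")
    name = schema.name
    strand = "unknown"
    if name == "SBS288":
        code, label96 = label.split(":", 1)
        strand = _STRAND_NAME[code]
        name = "SBS96"
        label = label96
    if name == "SBS96":
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        proto = dict(ref=ref, alt=alt, context5="TTTT" + five, context3=three + "TTTT")
    elif name == "DBS78":
        ref, alt = label.split(">")
        proto = dict(ref=ref, alt=alt, context5="TTTTT", context3="TTTTT")
    else:
        proto = _indel_prototype(label)
    return [
        MutationRecord(
            sample_id=sample_id,
            chrom=chrom,
            pos=start_pos + i,
            strand=strand,
            **proto,
        )
        for i in range(count)
    ]


def _indel_prototype(label: str) -> dict:
    size_s, kind, sub, num_s = label.split(":")
    size, num = int(size_s), int(num_s)
    if size == 1:
        base = sub  # C or T, already pyrimidine
        pad = "A" if base != "A" else "G"
        if kind == "Del":
            extra = num - 1  # adjacent copies beyond the deleted one
            ctx5 = pad * 12 + base * extra
            anchor = ctx5[-1] if extra == 0 else base
            # anchor must be the base 5' of the deleted one
            return dict(
                ref=anchor + base,
                alt=anchor,
                context5=ctx5[:-1] if extra == 0 else pad * 12 + base * (extra - 1),
                context3=pad * 12,
            )
        return dict(
            ref=pad,
            alt=pad + base,
            context5=pad * 11,
            context3=base * num + pad * 12,
        )
    unit = _UNITS[size if not (kind == "Del" and sub == "M" and num >= size) else size + 1]
    if kind == "Ins":
        return dict(
            ref="T",
            alt="T" + unit,
            context5="T" * 11,
            context3=unit * num + "T" * 12,
        )
    if sub == "R":
        return dict(
            ref="T" + unit,
            alt="T",
            context5="T" * 11,
            context3=unit * (num - 1) + "T" * 12,
        )
    # microhomology deletion: num bases of partial-unit homology 3' of the site
    return dict(
        ref="T" + unit,
        alt="T",
        context5="T" * 11,
        context3=unit[:num] + "T" * 12,
    )


def make_planted_signatures(
    schema: ChannelSchema | str,
    k: int,
    separation: float = 0.6,
    seed: int = 0,
    alpha: float = 0.3,
    max_tries: int = 2000,
) -> SignatureMatrix:
    """Random well-separated column-stochastic profiles.

    Profiles are Dirichlet draws (small ``alpha`` gives realistically
    peaked spectra) accepted greedily while all pairwise cosines stay at or
    below ``separation``; raises if the requested separation is infeasible
    within the retry budget.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    for _ in range(max_tries):
        p = rng.dirichlet(np.full(len(schema), alpha))
        if all(cosine_similarity(p, q) <= separation for q in kept):
            kept.append(p)
            if len(kept) == k:
                break
    if len(kept) < k:
        raise ValueError(
            f"could not find {k} profiles at separation {separation} "
            f"within {max_tries} tries"
        )
    return SignatureMatrix(
        schema, [f"P{i + 1}" for i in range(k)], np.column_stack(kept)
    )


def _shaped_profile(schema: ChannelSchema, heavy_class: str, weight: float) -> np.ndarray:
    """A peaked profile putting ``weight`` of its mass on one SBS class."""
    p = np.full(len(schema), (1 - weight) / (len(schema) - 16))
    idx = [i for i, c in enumerate(schema.channels) if c[2:5] == heavy_class]
    ramp = np.arange(1, len(idx) + 1, dtype=float) ** 2
    p[idx] = weight * ramp / ramp.sum()
    return p / p.sum()


def scenario_signatures() -> SignatureMatrix:
    """The three planted SBS-96 processes of the default geographic scenario.

    ``S_TA``: a T>A-dominated profile shaped like the aristolochic-acid
    signatures; ``S_TC``: a T>C-dominated profile shaped like the
    Japan-restricted signature; ``S_FLAT``: a featureless flat profile
    shaped like the ubiquitous clock-like background.
    """
    schema = get_schema("SBS96")
    profiles = np.column_stack(
        [
            _shaped_profile(schema, "T>A", 0.8),
            _shaped_profile(schema, "T>C", 0.8),
            np.full(96, 1.0 / 96),
        ]
    )
    return SignatureMatrix(schema, ["S_TA", "S_TC", "S_FLAT"], profiles)


@dataclass
class CountryConfig:
    """One country: incidence, cohort size, per-signature structure."""

    name: str
    asr: float  # age-standardized incidence rate per 100,000
    n_samples: int
    prevalence: dict[str, float]
    #: per-signature (median burden, log-sd) of the log-normal burden model
    burden: dict[str, tuple[float, float]]


@dataclass
class SimulationConfig:
    countries: list[CountryConfig]
    signatures: SignatureMatrix
    #: signature whose mean burden is linear in ASR: intercept + slope * asr
    asr_signature: str | None = None
    asr_intercept: float = 1500.0
    asr_slope: float = 150.0
    asr_sigma: float = 0.4
    #: odds-ratio effects of current smoking on per-signature presence
    smoking_or: dict[str, float] = field(default_factory=dict)
    male_fraction: float = 0.60
    age_mean: float = 62.0
    age_sd: float = 10.0
    smoking_probs: tuple[float, float, float] = (0.25, 0.25, 0.50)  # current/ex/never

    def __post_init__(self) -> None:
        names = set(self.signatures.names)
        for c in self.countries:
            unknown = set(c.prevalence) - names
            if unknown:
                raise ValueError(f"{c.name}: prevalence for unknown signatures {unknown}")
            if any(not 0 <= p <= 1 for p in c.prevalence.values()):
                raise ValueError(f"{c.name}: prevalences must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted per-sample exposures and covariates, for oracle checks."""

    exposures: pd.DataFrame  # samples x signatures, integer mutation counts
    cohort: pd.DataFrame
    channel_counts: pd.DataFrame | None = None  # channels x samples
    cluster_flags: dict[str, str] = field(default_factory=dict)

    def catalogue(self, schema: ChannelSchema | str):
        """The planted catalogue matrix (identical to rebuilding from records)."""
        from .catalogue import CatalogueMatrix

        if isinstance(schema, str):
            schema = get_schema(schema)
        return CatalogueMatrix.from_frame(self.channel_counts, schema)


def simulate_cohort(
    cfg: SimulationConfig, seed: int = 0, emit_records: bool = True
) -> tuple[list[MutationRecord], pd.DataFrame, GroundTruth]:
    """Draw a full synthetic cohort with exact exposure conservation.

    Per sample: the active signature set is Bernoulli per country
    prevalence (smoking odds-ratio effects applied on the logit scale),
    per-signature burdens are log-normal (the ASR-linked signature's mean
    is linear in country ASR), channel counts are multinomial given the
    burden, and each count is materialized as records via inverse
    classification — so rebuilding the catalogue reproduces the planted
    counts exactly. Large cohorts that only need the catalogue can pass
    ``emit_records=False``: the planted channel counts (identical to what
    the records would classify to) are always available on the returned
    :class:`GroundTruth`.
    """
    rng = np.random.default_rng(seed)
    sigs = cfg.signatures
    schema = sigs.schema
    records: list[MutationRecord] = []
    cohort_rows = []
    expo_rows = []
    channel_cols: dict[str, np.ndarray] = {}
    pos_counter = itertools.count(1000)
    chroms = [str(c) for c in range(1, 23)]
    for country in cfg.countries:
        for i in range(country.n_samples):
            sid = f"{country.name}_{i:04d}"
            sex = "male" if rng.random() < cfg.male_fraction else "female"
            age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18, 95))
            smoking = ("current", "ex", "never")[
                rng.choice(3, p=cfg.smoking_probs)
            ]
            exposures: dict[str, int] = {}
            for s in sigs.names:
                p = country.prevalence.get(s, 0.0)
                if s in cfg.smoking_or and smoking == "current" and 0 < p < 1:
                    odds = p / (1 - p) * cfg.smoking_or[s]
                    p = odds / (1 + odds)
                active = rng.random() < p
                if not active:
                    exposures[s] = 0
                    continue
                if s == cfg.asr_signature:
                    mean = cfg.asr_intercept + cfg.asr_slope * country.asr
                    mu = np.log(mean) - cfg.asr_sigma**2 / 2
                    burden = rng.lognormal(mu, cfg.asr_sigma)
                else:
                    median, sd = country.burden.get(s, (1000.0, 0.5))
                    burden = rng.lognormal(np.log(median), sd)
                exposures[s] = max(int(round(burden)), 1)
            sample_counts = np.zeros(len(schema), dtype=np.int64)
            for s, n in exposures.items():
                if n == 0:
                    continue
                sample_counts += rng.multinomial(n, sigs.profile(s))
            channel_cols[sid] = sample_counts
            if emit_records:
                for ch_idx in np.nonzero(sample_counts)[0]:
                    records.extend(
                        records_for_channel(
                            schema,
                            schema.channels[ch_idx],
                            sid,
                            count=int(sample_counts[ch_idx]),
                            chrom=chroms[ch_idx % len(chroms)],
                            start_pos=next(pos_counter) * 50,
                        )
                    )
            cohort_rows.append(
                {
                    "sample_id": sid,
                    "country": country.name,
                    "asr": country.asr,
                    "sex": sex,
                    "age_dx": age,
                    "smoking": smoking,
                }
            )
            expo_rows.append({"sample_id": sid, **exposures})
    cohort = pd.DataFrame(cohort_rows).set_index("sample_id")
    truth = (
        pd.DataFrame(expo_rows).set_index("sample_id").reindex(columns=sigs.names)
    )
    channel_counts = pd.DataFrame(channel_cols, index=list(schema.channels))
    return (
        records,
        cohort.reset_index(),
        GroundTruth(exposures=truth, cohort=cohort, channel_counts=channel_counts),
    )


# ---------------------------------------------------------------------------
# clonal / subclonal structure


@dataclass
class ClusterScenario:
    """Knobs of the clone/subclone simulator, including injected artifacts."""

    clonal_fraction: float = 0.65
    #: per-signature shift of relative activity, clone minus subclone
    deltas: dict[str, float] = field(default_factory=dict)
    frac_low_purity: float = 0.0
    frac_high_ccf_cluster: float = 0.0
    frac_chrx_cluster: float = 0.0
    frac_small_subclone: float = 0.0
    frac_bad_subclone: float = 0.0


def simulate_clusters(
    scenario: ClusterScenario,
    truth: GroundTruth,
    signatures: SignatureMatrix,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Clone/subclone structure for a simulated cohort.

    Every sample gets a clone near CCF 1 and one subclone in (0.1, 0.8];
    clonal and subclonal spectra are drawn from the sample's planted
    signature mix shifted by the configured deltas. Configurable fractions
    of samples receive filter-violating features (low purity, CCF > 1.5 or
    chrX-dominant artifact clusters, undersized or poorly separated
    subclones); the returned flags name the exclusion rule each such sample
    must trigger, and are exactly the oracle for the timing filters.

    Returns (cluster table, purity, clonal spectra, subclonal spectra,
    flags); spectra are channels x samples frames over retained-quality
    clusters only.
    """
    rng = np.random.default_rng(seed)
    schema = signatures.schema
    samples = list(truth.exposures.index)
    clusters = []
    purity = {}
    flags: dict[str, str] = {}
    clonal_spec = {}
    subclonal_spec = {}
    for sid in samples:
        expo = truth.exposures.loc[sid].to_numpy(dtype=float)
        total = int(expo.sum())
        if total == 0:
            continue
        w = expo / expo.sum()
        w_c, w_s = w.copy(), w.copy()
        for s, d in scenario.deltas.items():
            j = signatures.names.index(s)
            if w[j] > 0:
                w_c[j] = max(w[j] + d / 2, 0.0)
                w_s[j] = max(w[j] - d / 2, 0.0)
        w_c, w_s = w_c / w_c.sum(), w_s / w_s.sum()
        n_clonal = int(round(total * scenario.clonal_fraction))
        n_sub = total - n_clonal
        if rng.random() < scenario.frac_small_subclone:
            n_sub = int(rng.integers(20, 200))
            flags[sid] = "min_mutations"
        sub_ccf = float(rng.uniform(0.25, 0.70))
        if sid not in flags and rng.random() < scenario.frac_bad_subclone:
            sub_ccf = float(rng.uniform(0.81, 0.95))
            flags[sid] = "subclone_separation"
        pur = float(rng.uniform(0.5, 0.95))
        if sid not in flags and rng.random() < scenario.frac_low_purity:
            pur = float(rng.uniform(0.05, 0.39))
            flags[sid] = "purity"
        purity[sid] = pur
        clusters.append(
            {
                "sample_id": sid,
                "cluster_id": "clone",
                "ccf": float(np.clip(rng.normal(1.0, 0.03), 0.85, 1.15)),
                "n_mutations": n_clonal,
                "top_chrom": "1",
                "clonal": True,
            }
        )
        clusters.append(
            {
                "sample_id": sid,
                "cluster_id": "subclone1",
                "ccf": sub_ccf,
                "n_mutations": n_sub,
                "top_chrom": "2",
                "clonal": False,
            }
        )
        if rng.random() < scenario.frac_high_ccf_cluster:
            clusters.append(
                {
                    "sample_id": sid,
                    "cluster_id": "artifact_ccf",
                    "ccf": float(rng.uniform(1.6, 2.2)),
                    "n_mutations": int(rng.integers(50, 300)),
                    "top_chrom": "3",
                    "clonal": False,
                }
            )
        if rng.random() < scenario.frac_chrx_cluster:
            clusters.append(
                {
                    "sample_id": sid,
                    "cluster_id": "artifact_chrx",
                    "ccf": float(rng.uniform(0.3, 0.6)),
                    "n_mutations": int(rng.integers(50, 300)),
                    "top_chrom": "X",
                    "clonal": False,
                }
            )
        mix_c = signatures.profiles @ w_c
        mix_s = signatures.profiles @ w_s
        clonal_spec[sid] = rng.multinomial(n_clonal, mix_c)
        subclonal_spec[sid] = rng.multinomial(n_sub, mix_s)
    channels = list(schema.channels)
    clonal_df = pd.DataFrame(clonal_spec, index=channels)
    subclonal_df = pd.DataFrame(subclonal_spec, index=channels)
    return (
        pd.DataFrame(clusters),
        pd.Series(purity, name="purity"),
        clonal_df,
        subclonal_df,
        flags,
    )


# ---------------------------------------------------------------------------
# default geographic scenario

#: (name, ASR per 100,000, cohort size) of the 11 studied countries
DEFAULT_COUNTRIES = (
    ("Czechia", 14.4, 259),
    ("Russia", 10.3, 216),
    ("UK", 10.3, 115),
    ("Brazil", 4.5, 96),
    ("Canada", 10.4, 73),
    ("Serbia", 7.4, 69),
    ("Romania", 7.7, 64),
    ("Japan", 7.6, 36),
    ("Lithuania", 14.5, 16),
    ("Poland", 8.1, 13),
    ("Thailand", 1.8, 5),
)

#: countries carrying the T>A process, with its prevalence there
TA_PREVALENCE = {"Romania": 0.70, "Serbia": 0.23, "Thailand": 0.60}
#: the T>C process is essentially restricted to one country
TC_PREVALENCE = {"Japan": 0.72}
_BACKGROUND_PREVALENCE = 0.02


def default_scenario(scale: float = 1.0) -> SimulationConfig:
    """The 11-country scenario the cohort structure emulates.

    A T>A signature concentrated in Romania/Serbia/Thailand, a T>C
    signature at 72% prevalence in Japan and 2% elsewhere, and a flat
    ubiquitous signature whose mean burden is linear in the country's ASR.
    ``scale`` shrinks per-country cohort sizes proportionally (minimum 3)
    for desk-scale runs.
    """
    sigs = scenario_signatures()
    countries = []
    for name, asr, n in DEFAULT_COUNTRIES:
        countries.append(
            CountryConfig(
                name=name,
                asr=asr,
                n_samples=max(int(round(n * scale)), 3),
                prevalence={
                    "S_TA": TA_PREVALENCE.get(name, _BACKGROUND_PREVALENCE),
                    "S_TC": TC_PREVALENCE.get(name, _BACKGROUND_PREVALENCE),
                    "S_FLAT": 1.0,
                },
                burden={"S_TA": (4000.0, 1.0), "S_TC": (800.0, 0.6)},
            )
        )
    return SimulationConfig(
        countries=countries,
        signatures=sigs,
        asr_signature="S_FLAT",
        asr_intercept=1500.0,
        asr_slope=150.0,
    )
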