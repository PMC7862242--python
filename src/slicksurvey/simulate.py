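"""Synthetic paired slick/ambient tow surveys with known ground truth.

The generator emulates the statistical structure of a nearshore neuston
survey: 80 slick and 54 ambient tows (52 of them paired), tow volumes from
a truncated log-normal centred near 390 m^3 (a 0.79 m^2 net mouth towed
~495 m), per-taxon counts from a negative binomial whose mean is
volume x base ambient density x enrichment (enrichment applied in slicks
only), right-skewed fish lengths with a logit-linear slick-occurrence
gradient in length, and per-habitat log-normal debris masses. Every
generating parameter is returned in a truth record so downstream estimators
have parameter-recovery tests.

Each taxon draws from its own child of one :class:`numpy.random.SeedSequence`,
so adding or removing a taxon does not perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import Survey


@dataclass
class TaxonSpec:
    taxon_id: str
    family: str
    natal_habitat: str
    functional_group: str
    base_ambient_density: float     # individuals per m^3 in ambient water
    enrichment_ratio: float         # slick mean density multiplier, >= 0
    dispersion: float = 0.7         # negative-binomial size parameter k > 0

    def __post_init__(self) -> None:
        if self.base_ambient_density < 0 or self.enrichment_ratio < 0:
            raise ValueError(f"{self.taxon_id}: densities and ratios must be >= 0")
        if self.dispersion <= 0:
            raise ValueError(f"{self.taxon_id}: dispersion must be > 0")


@dataclass
class SizeModel:
    """Length distribution and size-dependent slick occurrence.

    Lengths are geometric over integer mm bins (strongly right-skewed, as
    larval length frequencies are); the probability that a fish of length L
    occupies a slick rather than ambient water follows
    inverse-logit(logit_intercept + logit_slope * L), up to an intercept
    shift induced by the overall fish enrichment (reported in the truth
    record as ``effective_intercept``).
    """

    logit_intercept: float = -2.0
    logit_slope: float = 0.1        # per mm: a gradual rise, ~0.75 at small
                                    # sizes to ~0.99 by 40 mm once the
                                    # overall enrichment shift is added
    mean_length_mm: float = 6.0
    max_length_mm: int = 60

    def length_pmf(self) -> np.ndarray:
        """Geometric pmf over lengths 1..max_length_mm."""
        if self.mean_length_mm <= 1:
            raise ValueError("mean_length_mm must exceed 1")
        q = 1.0 / self.mean_length_mm
        L = np.arange(1, self.max_length_mm + 1)
        pmf = q * (1 - q) ** (L - 1)
        return pmf / pmf.sum()


@dataclass
class DebrisModel:
    """Log-normal dry-weight density (mg m^-3) parameters per habitat.

    Defaults put the plastic slick:ambient mass ratio near 260x and the
    organic ratio near 30x, with unit log-SD scatter.
    """

    organic_logmean: dict = field(
        default_factory=lambda: {"slick": np.log(16.96) - 0.5, "ambient": np.log(0.51) - 0.5}
    )
    plastic_logmean: dict = field(
        default_factory=lambda: {"slick": np.log(26.33) - 0.5, "ambient": np.log(0.10) - 0.5}
    )
    log_sd: float = 1.0


@dataclass
class VolumeModel:
    """Tow volume (m^3): log-normal truncated below at ``min_volume``."""

    mean_m3: float = 390.0          # 0.79 m^2 mouth x ~495 m tow
    log_sd: float = 0.3
    min_volume: float = 50.0


@dataclass
class SimConfig:
    n_slick: int = 80
    n_ambient: int = 54
    n_pairs: int = 52
    n_sites: int = 8
    taxa: list[TaxonSpec] = field(default_factory=list)
    size_model: SizeModel = field(default_factory=SizeModel)
    debris_model: DebrisModel = field(default_factory=DebrisModel)
    volume_model: VolumeModel = field(default_factory=VolumeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slick < 1 or self.n_ambient < 1:
            raise ValueError("need at least one tow per habitat")
        if self.n_pairs > min(self.n_slick, self.n_ambient):
            raise ValueError("n_pairs cannot exceed the smaller habitat count")


def default_taxa() -> list[TaxonSpec]:
    """A 54-fish-family community echoing a nearshore neuston survey:
    33 common families from three natal habitats with slick enrichments
    spanning ~1-100x plus 21 rare families (expected in fewer than 4 tows,
    so the rarity filter has work to do); invertebrate larvae 2-10x,
    holozooplankton ~2-7x, eggs ~3x, insects ~27x.
    """
    taxa: list[TaxonSpec] = []
    natal = ["coral_reef", "epipelagic", "deep_water"]
    # 33 common fish families; enrichment log-spaced 1.2-100, a few below 2
    enrich = np.round(np.geomspace(1.2, 100.0, 33), 2)
    base = np.round(np.geomspace(0.002, 0.08, 33), 5)
    for i, (e, b) in enumerate(zip(enrich, base[::-1])):
        taxa.append(TaxonSpec(
            taxon_id=f"fish_fam_{i:02d}", family=f"fish_fam_{i:02d}",
            natal_habitat=natal[i % 3], functional_group="fish",
            base_ambient_density=float(b), enrichment_ratio=float(e),
        ))
    # 21 rare fish families, mostly seen in 0-3 tows of a 134-tow survey
    rare_base = np.round(np.geomspace(2e-6, 1.5e-5, 21), 8)
    rare_enrich = np.round(np.geomspace(1.5, 12.0, 21), 2)
    for i, (b, e) in enumerate(zip(rare_base[::-1], rare_enrich)):
        taxa.append(TaxonSpec(
            taxon_id=f"fish_rare_{i:02d}", family=f"fish_rare_{i:02d}",
            natal_habitat=natal[i % 3], functional_group="fish",
            base_ambient_density=float(b), enrichment_ratio=float(e),
        ))
    for i, e in enumerate([2.0, 3.1, 4.5, 6.1, 6.2, 6.3, 7.6, 10.1]):
        taxa.append(TaxonSpec(
            taxon_id=f"invert_{i}", family=f"invert_fam_{i}",
            natal_habitat="other", functional_group="invertebrate_larva",
            base_ambient_density=0.05, enrichment_ratio=e,
        ))
    for i, e in enumerate([2.2, 3.5, 4.0, 6.6]):
        taxa.append(TaxonSpec(
            taxon_id=f"holo_{i}", family=f"holo_fam_{i}",
            natal_habitat="other", functional_group="holozooplankton",
            base_ambient_density=0.5, enrichment_ratio=e,
        ))
    taxa.append(TaxonSpec(
        taxon_id="fish_eggs", family="egg", natal_habitat="other",
        functional_group="egg", base_ambient_density=2.85, enrichment_ratio=3.1,
    ))
    taxa.append(TaxonSpec(
        taxon_id="insects", family="insect", natal_habitat="other",
        functional_group="insect", base_ambient_density=0.003,
        enrichment_ratio=26.6,
    ))
    return taxa


def default_config(seed: int = 0, **overrides) -> SimConfig:
    cfg = SimConfig(taxa=default_taxa(), seed=seed)
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown SimConfig field {key!r}")
        setattr(cfg, key, value)
    return cfg


def _negative_binomial(rng, mean: np.ndarray, k: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion k (variance mu + mu^2/k)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if pos.any():
        p = k / (k + mean[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def simulate_survey(config: SimConfig) -> tuple[Survey, dict]:
    """Generate one survey; returns (Survey, truth record).

    The truth record carries every generating parameter, the realized tow
    volumes, per-taxon (base density, enrichment, dispersion), the debris
    mean densities per habitat, and the effective logit-linear occurrence
    curve for fish length (slope = configured slope; intercept shifted by
    the log of the aggregate fish enrichment and the length-reweighting
    normalizers).
    """
    root = np.random.SeedSequence(config.seed)
    streams = {
        "tows": np.random.default_rng(root.spawn(1)[0]),
        "debris": np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(10**6,))
        ),
    }

    habitats = ["slick"] * config.n_slick + ["ambient"] * config.n_ambient
    n = len(habitats)
    tow_ids = [f"t{i:03d}" for i in range(n)]
    rng_t = streams["tows"]
    vm = config.volume_model
    mu_log = np.log(vm.mean_m3) - 0.5 * vm.log_sd**2
    volumes = rng_t.lognormal(mu_log, vm.log_sd, size=n)
    for _ in range(100):
        bad = volumes <= vm.min_volume
        if not bad.any():
            break
        volumes[bad] = rng_t.lognormal(mu_log, vm.log_sd, size=int(bad.sum()))
    volumes = np.maximum(volumes, vm.min_volume)

    sites = [f"site_{i % config.n_sites}" for i in range(n)]
    rng_t.shuffle(sites)
    pair_ids = [None] * n
    for p in range(config.n_pairs):
        pair_ids[p] = f"pair_{p:02d}"                     # slick member
        pair_ids[config.n_slick + p] = f"pair_{p:02d}"    # ambient member
    years = rng_t.choice([2016, 2017, 2018], size=n)
    days = rng_t.integers(1, 30, size=n)
    minutes = rng_t.integers(-240, 241, size=n)
    gear = rng_t.choice(["ring_net_1m", "ik_trawl"], size=n, p=[0.88, 0.12])
    order = rng_t.choice(["slick_first", "ambient_first"], size=n, p=[0.8, 0.2])

    tows = pd.DataFrame({
        "tow_id": tow_ids, "habitat": habitats, "site": sites,
        "pair_id": pair_ids, "year": years, "day": days,
        "minutes_from_solar_noon": minutes, "gear": gear,
        "sampling_order": order,
        "volume_filtered_m3": np.round(volumes, 2),
        "tow_length_m": np.round(volumes / 0.79, 1),
    })
    volumes = tows["volume_filtered_m3"].to_numpy()
    is_slick = np.asarray([h == "slick" for h in habitats])

    # fish length pmfs per habitat (shared across fish taxa)
    sm_ = config.size_model
    pmf = sm_.length_pmf()
    L = np.arange(1, sm_.max_length_mm + 1)
    sigma = expit(sm_.logit_intercept + sm_.logit_slope * L)
    w_slick = pmf * sigma
    w_ambient = pmf * (1.0 - sigma)
    Zs, Za = w_slick.sum(), w_ambient.sum()
    pmf_slick = w_slick / Zs
    pmf_ambient = w_ambient / Za

    count_rows = []
    for idx, spec in enumerate(config.taxa):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(idx,))
        )
        mean = volumes * spec.base_ambient_density * np.where(
            is_slick, spec.enrichment_ratio, 1.0
        )
        counts = _negative_binomial(rng, mean, spec.dispersion)
        for t, c in zip(range(n), counts):
            if c == 0:
                continue
            if spec.functional_group == "fish":
                p = pmf_slick if is_slick[t] else pmf_ambient
                lengths = rng.choice(L, size=int(c), p=p)
                uniq, reps = np.unique(lengths, return_counts=True)
                for length, k in zip(uniq, reps):
                    count_rows.append((tow_ids[t], spec.taxon_id, "larva",
                                       int(k), float(length)))
            else:
                count_rows.append((tow_ids[t], spec.taxon_id, None, int(c), None))
    counts = pd.DataFrame(
        count_rows,
        columns=["tow_id", "taxon_id", "life_stage", "count", "total_length_mm"],
    )

    dm = config.debris_model
    rng_d = streams["debris"]
    debris_rows = []
    for cat, logmeans in (("organic", dm.organic_logmean),
                          ("plastic", dm.plastic_logmean)):
        for t in range(n):
            hab = habitats[t]
            dens = rng_d.lognormal(logmeans[hab], dm.log_sd)
            debris_rows.append((tow_ids[t], cat, round(dens * volumes[t], 3)))
    debris = pd.DataFrame(debris_rows, columns=["tow_id", "category", "dry_weight_mg"])

    taxa_table = pd.DataFrame([
        {
            "taxon_id": s.taxon_id, "rank": "family", "family": s.family,
            "natal_habitat": s.natal_habitat,
            "functional_group": s.functional_group, "fishery_flag": False,
        }
        for s in config.taxa
    ])

    fish = [s for s in config.taxa if s.functional_group == "fish"]
    D_a = sum(s.base_ambient_density for s in fish)
    D_s = sum(s.base_ambient_density * s.enrichment_ratio for s in fish)
    eff_intercept = (
        sm_.logit_intercept + float(np.log((D_s / Zs) / (D_a / Za)))
        if fish and D_a > 0 else float("nan")
    )
    truth = {
        "seed": config.seed,
        "n_slick": config.n_slick, "n_ambient": config.n_ambient,
        "taxa": {
            s.taxon_id: {
                "base_ambient_density": s.base_ambient_density,
                "enrichment_ratio": s.enrichment_ratio,
                "dispersion": s.dispersion,
                "functional_group": s.functional_group,
            } for s in config.taxa
        },
        "size": {
            "logit_intercept": sm_.logit_intercept,
            "logit_slope": sm_.logit_slope,
            "effective_intercept": eff_intercept,
            "mean_length_mm": sm_.mean_length_mm,
        },
        "debris": {
            cat: {
                hab: float(np.exp(lm[hab] + 0.5 * dm.log_sd**2))
                for hab in ("slick", "ambient")
            }
            for cat, lm in (("organic", dm.organic_logmean),
                            ("plastic", dm.plastic_logmean))
        },
        "volume_model": asdict(config.volume_model),
    }
    survey = Survey(tows=tows, counts=counts, taxa=taxa_table, debris=debris)
    return survey, truth


def worked_example_fixture() -> Survey:
    """Tiny deterministic survey whose group means equal round headline
    values: all-debris dry weight 43.31 / 0.61 mg m^-3 (slick/ambient),
    plastic 26.33 / 0.10, fish-egg densities 8.85 / 2.85 m^-3, and mean fish
    lengths 6.11 / 5.33 mm. Useful for exercising the point-estimate ratio
    arithmetic (71.0x debris, 263.3x plastic, 3.1x eggs, 14.6% longer fish).

    Synthetic: constructed so its means match the printed values; it is not
    field data.
    """
    vol = 100.0
    tow_ids = [f"s{i}" for i in range(4)] + [f"a{i}" for i in range(4)]
    tows = pd.DataFrame({
        "tow_id": tow_ids,
        "habitat": ["slick"] * 4 + ["ambient"] * 4,
        "site": ["wex"] * 8,
        "pair_id": [f"p{i}" for i in range(4)] * 2,
        "year": [2018] * 8,
        "minutes_from_solar_noon": [0] * 8,
        "gear": ["ring_net_1m"] * 8,
        "volume_filtered_m3": [vol] * 8,
    })
    egg_counts_slick = [885, 885, 800, 970]      # mean density 8.85 m^-3
    egg_counts_ambient = [285, 285, 250, 320]    # mean density 2.85 m^-3
    rows = []
    for tid, c in zip(tow_ids[:4], egg_counts_slick):
        rows.append((tid, "fish_eggs", "egg", c, None))
    for tid, c in zip(tow_ids[4:], egg_counts_ambient):
        rows.append((tid, "fish_eggs", "egg", c, None))
    # slick lengths: 89 x 6 mm + 11 x 7 mm -> mean 6.11; ambient: 67 x 5 + 33 x 6 -> 5.33
    slick_lengths = [("s0", 6, 25), ("s0", 7, 3), ("s1", 6, 25), ("s1", 7, 3),
                     ("s2", 6, 25), ("s2", 7, 3), ("s3", 6, 14), ("s3", 7, 2)]
    ambient_lengths = [("a0", 5, 17), ("a0", 6, 9), ("a1", 5, 17), ("a1", 6, 8),
                       ("a2", 5, 17), ("a2", 6, 8), ("a3", 5, 16), ("a3", 6, 8)]
    for tid, length, k in slick_lengths + ambient_lengths:
        rows.append((tid, "fish_larvae", "larva", k, float(length)))
    counts = pd.DataFrame(
        rows, columns=["tow_id", "taxon_id", "life_stage", "count", "total_length_mm"]
    )
    taxa = pd.DataFrame([
        {"taxon_id": "fish_eggs", "rank": "group", "family": "egg",
         "natal_habitat": "other", "functional_group": "egg", "fishery_flag": False},
        {"taxon_id": "fish_larvae", "rank": "group", "family": "fish",
         "natal_habitat": "other", "functional_group": "fish", "fishery_flag": False},
    ])
    debris_rows = []
    plastic_slick = [2633, 2633, 2533, 2733]     # mg; mean density 26.33 mg m^-3
    organic_slick = [1698, 1698, 1598, 1798]     # mean 16.98 -> total 43.31
    plastic_ambient = [10, 10, 8, 12]            # mean 0.10
    organic_ambient = [51, 51, 41, 61]           # mean 0.51 -> total 0.61
    for tid, w in zip(tow_ids[:4], plastic_slick):
        debris_rows.append((tid, "plastic", w))
    for tid, w in zip(tow_ids[:4], organic_slick):
        debris_rows.append((tid, "organic", w))
    for tid, w in zip(tow_ids[4:], plastic_ambient):
        debris_rows.append((tid, "plastic", w))
    for tid, w in zip(tow_ids[4:], organic_ambient):
        debris_rows.append((tid, "organic", w))
    debris = pd.DataFrame(debris_rows, columns=["tow_id", "category", "dry_weight_mg"])
    return Survey(tows=tows, counts=counts, taxa=taxa, debris=debris)
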