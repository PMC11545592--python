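"""Synthetic faecal-metabarcoding datasets with known truth.

The generator emulates the structure of a predator faecal COI amplicon
study: a modest number of faecal samples sequenced to a deep,
heterogeneous per-sample depth, dominated by host (predator) reads
because blocking primers are often ineffective, with the prey signal
spread over a set of genus-level items and a tail of sub-threshold
contaminant/noise OTUs.

Per sample k the model is:

* depth ~ NegativeBinomial(mean, dispersion) (lognormal alternative);
* incidence z_{i,k} ~ Bernoulli(psi_i) per prey item; samples that draw
  no prey at all have their incidence row redrawn so the configured
  sample count is retained (logged);
* composition of the present items ~ Dirichlet(alpha * mean shares of
  the present items, renormalised);
* reads are allocated multinomially among the host OTU
  (``host_fraction`` of the probability mass), the noise OTUs
  (``noise_share`` split evenly), and the prey OTUs (each item's
  probability split evenly over its ``n_otus`` OTUs).

Each prey OTU receives a BLAST-style best hit with an identity drawn
from the profile's identity range; noise OTUs cycle through the failure
modes a real hit table shows (no hit row at all, an explicit
``"no match"``, fungal / Chromista / livestock contaminants, and a
plausible prey taxon at sub-threshold identity). The field survey is
drawn around per-taxon availability weights and includes field-only
taxa so that negative selectivity (D = -1) is exercised.

The returned :class:`SyntheticTruth` records the incidence matrix, the
realised prey composition per sample, and the expected %FOO (100 psi_i)
and expected %RRA per item, so pipeline estimates can be scored against
the generating process.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GROUP_FISH,
    GROUP_INVERT,
    NO_MATCH,
    FieldSurveyTable,
    PreyTable,
    ReadCountTable,
    TaxonomyHit,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreyProfile:
    """Generating parameters for one (genus-level) prey item.

    ``name`` is the item label the pipeline should recover (e.g.
    ``"Zacco sp."``); ``taxon`` is the binomial written into the hit
    table (defaults to ``name``). ``occurrence_prob`` (psi) is the
    per-sample presence probability and ``mean_diet_share`` the item's
    mean share of prey reads conditional on presence (shares are
    renormalised over the set of present items). ``in_field_survey``
    controls whether the species is listed in the generated survey,
    exercising the species -> genus demotion path when False.
    """

    name: str
    prey_group: str
    occurrence_prob: float
    mean_diet_share: float
    n_otus: int = 1
    identity_range: tuple[float, float] = (97.5, 100.0)
    taxon: str | None = None
    in_field_survey: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.occurrence_prob <= 1.0:
            raise ValidationError(f"{self.name}: occurrence_prob outside [0, 1]")
        if self.mean_diet_share <= 0:
            raise ValidationError(f"{self.name}: mean_diet_share must be > 0")
        if self.n_otus < 1:
            raise ValidationError(f"{self.name}: n_otus must be >= 1")

    @property
    def hit_taxon(self) -> str:
        return self.taxon if self.taxon is not None else self.name

    @property
    def genus(self) -> str:
        return self.name.split()[0]


#: thirteen genus-level items in two groups: one dominant fish, a few
#: moderately common items, and a tail of occasional prey
DEFAULT_PROFILES: tuple[PreyProfile, ...] = (
    PreyProfile("Zacco sp.", GROUP_FISH, 1.0, 0.40, n_otus=2, taxon="Zacco temminckii"),
    PreyProfile("Rhinogobius sp.", GROUP_FISH, 0.55, 0.08, taxon="Rhinogobius brunneus"),
    PreyProfile("Micropterus sp.", GROUP_FISH, 0.35, 0.08, taxon="Micropterus salmoides"),
    PreyProfile("Misgurnus sp.", GROUP_FISH, 0.20, 0.05, taxon="Misgurnus anguillicaudatus"),
    PreyProfile("Carassius sp.", GROUP_FISH, 0.20, 0.05, taxon="Carassius cuvieri"),
    PreyProfile("Hemibarbus sp.", GROUP_FISH, 0.15, 0.04, taxon="Hemibarbus labeo"),
    PreyProfile("Polypedilum sp.", GROUP_INVERT, 0.60, 0.08, n_otus=2, taxon="Polypedilum japonicum"),
    PreyProfile("Ephemera sp.", GROUP_INVERT, 0.50, 0.08, taxon="Ephemera orientalis"),
    PreyProfile("Chironomus sp.", GROUP_INVERT, 0.30, 0.04, taxon="Chironomus flaviplumus"),
    PreyProfile("Cricotopus sp.", GROUP_INVERT, 0.20, 0.04, taxon="Cricotopus triannulatus"),
    # species deliberately absent from the generated survey: the survey
    # lists a congener instead, exercising the demotion-to-genus path
    PreyProfile("Radix sp.", GROUP_INVERT, 0.20, 0.02, taxon="Radix plicatula",
                in_field_survey=False),
    PreyProfile("Platycnemis sp.", GROUP_INVERT, 0.15, 0.02, taxon="Platycnemis phyllopoda"),
    PreyProfile("Limnodrilus sp.", GROUP_INVERT, 0.15, 0.02, taxon="Limnodrilus sp."),
)

#: taxa recorded in the field but never eaten, per group (negative selection)
DEFAULT_FIELD_ONLY: tuple[tuple[str, str], ...] = (
    (GROUP_FISH, "Squalidus"),
    (GROUP_FISH, "Opsariichthys"),
    (GROUP_INVERT, "Baetis"),
    (GROUP_INVERT, "Hydropsyche"),
    (GROUP_INVERT, "Physa"),
)

_NOISE_TAXA_CYCLE = (
    None,  # OTU absent from the hit table: synthesised as "no match"
    NO_MATCH,
    "Fungi sp.",
    "Chromista sp.",
    "Bos taurus",
    "__low_identity_prey__",  # plausible prey taxon below the identity floor
)


@dataclass
class SyntheticConfig:
    """Study conditions for one generated dataset.

    Defaults mirror a 24-sample faecal study sequenced to a few hundred
    thousand reads per sample with heavy host carryover and a tail of
    sub-threshold noise OTUs (each noise OTU's expected share is
    ``noise_share / noise_otu_count`` = 0.005% by default, half the
    0.01% filtering threshold).
    """

    n_samples: int = 24
    depth_mean: float = 300_000.0
    depth_dispersion: float = 5.0
    depth_model: str = "negative_binomial"  # or "lognormal"
    host_fraction: float = 0.70
    host_taxon: str = "Odontobutis obscurus"
    noise_otu_count: int = 40
    noise_share: float = 0.002
    dirichlet_concentration: float = 30.0
    field_mean_count: int = 60
    field_only_taxa: tuple[tuple[str, str], ...] = DEFAULT_FIELD_ONLY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0.0 <= self.host_fraction < 1.0:
            raise ValidationError("host_fraction must be in [0, 1)")
        if not 0.0 <= self.noise_share < 1.0:
            raise ValidationError("noise_share must be in [0, 1)")
        if self.host_fraction + self.noise_share >= 1.0:
            raise ValidationError("host_fraction + noise_share must be < 1")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be > 0")
        if self.depth_model not in ("negative_binomial", "lognormal"):
            raise ValidationError(f"unknown depth_model {self.depth_model!r}")


@dataclass
class SyntheticTruth:
    """Generating truth for one dataset, keyed by prey-item name."""

    incidence: pd.DataFrame  # samples x items, 0/1
    composition: pd.DataFrame  # samples x items, prey-read shares (rows sum to 1)
    expected_foo: pd.Series  # 100 * psi per item
    expected_rra: pd.Series  # realised mean composition * 100 per item
    host_otu_id: str
    noise_otu_ids: list[str]
    item_otu_ids: dict[str, list[str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "incidence": self.incidence.to_dict(orient="index"),
            "composition": {
                k: {i: float(v) for i, v in row.items()}
                for k, row in self.composition.to_dict(orient="index").items()
            },
            "expected_foo": {k: float(v) for k, v in self.expected_foo.items()},
            "expected_rra": {k: float(v) for k, v in self.expected_rra.items()},
            "host_otu_id": self.host_otu_id,
            "noise_otu_ids": self.noise_otu_ids,
            "item_otu_ids": self.item_otu_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticDataset:
    table: ReadCountTable
    hits: list[TaxonomyHit]
    survey: FieldSurveyTable
    truth: SyntheticTruth
    config: SyntheticConfig


def _draw_depths(rng: np.random.Generator, config: SyntheticConfig) -> np.ndarray:
    if config.depth_model == "negative_binomial":
        k = config.depth_dispersion
        p = k / (k + config.depth_mean)
        depths = rng.negative_binomial(k, p, size=config.n_samples)
    else:
        sigma = np.sqrt(np.log1p(1.0 / config.depth_dispersion))
        mu = np.log(config.depth_mean) - sigma**2 / 2.0
        depths = rng.lognormal(mu, sigma, size=config.n_samples).astype(np.int64)
    return np.maximum(depths, 1_000)  # floor: a failed library would be resequenced


def generate_dataset(
    config: SyntheticConfig | None = None,
    profiles: tuple[PreyProfile, ...] | list[PreyProfile] = DEFAULT_PROFILES,
) -> SyntheticDataset:
    """Draw one dataset: count table, hit table, survey and truth."""
    config = config or SyntheticConfig()
    profiles = tuple(profiles)
    if not profiles:
        raise ValidationError("at least one prey profile is required")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValidationError("prey profile names must be unique")
    psi = np.array([p.occurrence_prob for p in profiles])
    if np.all(psi == 0):
        raise ValidationError("all occurrence probabilities are zero")
    mean_shares = np.array([p.mean_diet_share for p in profiles])
    mean_shares = mean_shares / mean_shares.sum()

    rng = np.random.default_rng(config.seed)
    n_items = len(profiles)
    samples = [f"S{k + 1:03d}" for k in range(config.n_samples)]

    # OTU layout: prey OTUs, then host, then noise
    item_otus: dict[str, list[str]] = {}
    otu_ids: list[str] = []
    counter = 1
    for p in profiles:
        ids = [f"OTU{counter + j:04d}" for j in range(p.n_otus)]
        counter += p.n_otus
        item_otus[p.name] = ids
        otu_ids.extend(ids)
    host_otu = f"OTU{counter:04d}"
    counter += 1
    noise_otus = [f"OTU{counter + j:04d}" for j in range(config.noise_otu_count)]
    otu_ids.append(host_otu)
    otu_ids.extend(noise_otus)

    depths = _draw_depths(rng, config)

    # incidence, with redraws for all-empty samples so S stays fixed
    incidence = rng.random((config.n_samples, n_items)) < psi
    redraws = 0
    for k in range(config.n_samples):
        while not incidence[k].any():
            incidence[k] = rng.random(n_items) < psi
            redraws += 1
            if redraws > 10_000:
                raise ValidationError("cannot draw a non-empty sample; psi too small")
    if redraws:
        logger.info("redrew incidence for empty samples %d time(s)", redraws)

    alpha0 = config.dirichlet_concentration
    composition = np.zeros((config.n_samples, n_items))
    counts = np.zeros((config.n_samples, len(otu_ids)), dtype=np.int64)
    prey_mass = 1.0 - config.host_fraction - config.noise_share
    noise_p = (
        np.full(config.noise_otu_count, config.noise_share / config.noise_otu_count)
        if config.noise_otu_count
        else np.empty(0)
    )
    col_of = {otu: j for j, otu in enumerate(otu_ids)}
    for k in range(config.n_samples):
        present = np.flatnonzero(incidence[k])
        alpha = alpha0 * mean_shares[present] / mean_shares[present].sum()
        comp = rng.dirichlet(alpha)
        composition[k, present] = comp
        probs = np.zeros(len(otu_ids))
        for idx, frac in zip(present, comp):
            ids = item_otus[profiles[idx].name]
            for otu in ids:
                probs[col_of[otu]] = prey_mass * frac / len(ids)
        probs[col_of[host_otu]] = config.host_fraction
        for j, otu in enumerate(noise_otus):
            probs[col_of[otu]] = noise_p[j]
        counts[k] = rng.multinomial(depths[k], probs / probs.sum())

    table = ReadCountTable(pd.DataFrame(counts, index=samples, columns=otu_ids))

    # taxonomy hits
    hits: list[TaxonomyHit] = []
    acc = 1
    for p in profiles:
        for otu in item_otus[p.name]:
            ident = float(rng.uniform(*p.identity_range))
            hits.append(
                TaxonomyHit(
                    otu_id=otu,
                    taxon=p.hit_taxon,
                    percent_identity=round(ident, 1),
                    query_coverage_pct=100.0,
                    max_score=float(round(450 + ident, 0)),
                    accession=f"SYN{acc:06d}.1",
                )
            )
            acc += 1
    hits.append(
        TaxonomyHit(host_otu, config.host_taxon, 100.0, 100.0, 579.0, f"SYN{acc:06d}.1")
    )
    acc += 1
    prey_taxa = [p.hit_taxon for p in profiles]
    for j, otu in enumerate(noise_otus):
        kind = _NOISE_TAXA_CYCLE[j % len(_NOISE_TAXA_CYCLE)]
        if kind is None:
            continue  # no hit row: reader path synthesises "no match"
        if kind == "__low_identity_prey__":
            taxon = prey_taxa[j % len(prey_taxa)]
            ident = float(round(rng.uniform(85.0, 96.9), 1))
        elif kind == NO_MATCH:
            taxon, ident = NO_MATCH, 0.0
        else:
            taxon = kind
            ident = float(round(rng.uniform(97.0, 100.0), 1))
        hits.append(
            TaxonomyHit(otu, taxon, ident, 100.0, float(round(300 + ident, 0)), f"SYN{acc:06d}.1")
        )
        acc += 1

    # field survey drawn around availability weights
    records = []
    for p in profiles:
        if not p.in_field_survey:
            continue
        species = p.hit_taxon if not p.hit_taxon.split()[-1].startswith("sp") else ""
        count = 1 + int(rng.poisson(config.field_mean_count))
        records.append(
            {"group": p.prey_group, "genus": p.genus, "species": species, "count": count}
        )
    # a congener for any profile kept out of the survey, so its genus exists
    for p in profiles:
        if p.in_field_survey:
            continue
        records.append(
            {
                "group": p.prey_group,
                "genus": p.genus,
                "species": f"{p.genus} auricularia",
                "count": 1 + int(rng.poisson(config.field_mean_count)),
            }
        )
    for group, genus in config.field_only_taxa:
        records.append(
            {
                "group": group,
                "genus": genus,
                "species": "",
                "count": 1 + int(rng.poisson(config.field_mean_count)),
            }
        )
    survey = FieldSurveyTable(pd.DataFrame(records))

    comp_df = pd.DataFrame(composition, index=samples, columns=names)
    truth = SyntheticTruth(
        incidence=pd.DataFrame(incidence.astype(int), index=samples, columns=names),
        composition=comp_df,
        expected_foo=pd.Series(100.0 * psi, index=names, name="expected_foo"),
        expected_rra=pd.Series(
            100.0 * comp_df.to_numpy().mean(axis=0), index=names, name="expected_rra"
        ),
        host_otu_id=host_otu,
        noise_otu_ids=noise_otus,
        item_otu_ids=item_otus,
    )
    return SyntheticDataset(table=table, hits=hits, survey=survey, truth=truth, config=config)


def recovery_report(truth: SyntheticTruth, metrics: pd.DataFrame) -> pd.DataFrame:
    """Deviation of pipeline %FOO/%RRA estimates from the generating truth.

    ``metrics`` is the output of :func:`dietmb.metrics.metrics_report` on
    the dataset run through the full pipeline. Items in the metrics table
    that the generator never produced raise an error; truth items the
    pipeline failed to detect are scored with observed values of 0.
    ``foo_se`` is the binomial standard error of %FOO at S samples.
    """
    truth_items = list(truth.expected_foo.index)
    unknown = [i for i in metrics["item"] if i not in truth_items]
    if unknown:
        raise ValidationError(f"metrics contain item(s) unknown to the truth: {unknown}")
    n_samples = truth.incidence.shape[0]
    observed = metrics.set_index("item")
    rows = []
    for item in truth_items:
        psi = truth.expected_foo[item] / 100.0
        foo_obs = float(observed["pct_foo"].get(item, 0.0))
        rra_obs = float(observed["pct_rra"].get(item, 0.0))
        rows.append(
            {
                "item": item,
                "expected_foo": float(truth.expected_foo[item]),
                "observed_foo": foo_obs,
                "foo_abs_dev": abs(foo_obs - truth.expected_foo[item]),
                "foo_se": 100.0 * np.sqrt(psi * (1.0 - psi) / n_samples),
                "expected_rra": float(truth.expected_rra[item]),
                "observed_rra": rra_obs,
                "rra_abs_dev": abs(rra_obs - truth.expected_rra[item]),
            }
        )
    return pd.DataFrame(rows)


def config_to_json(config: SyntheticConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=1, sort_keys=True))
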