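"""Synthetic study inputs with known ground truth.

Generates annotation-by-sample count tables, sample metadata, UniProt->GO
mapping tables and plant-trait tables that emulate the statistical
structure of drought / well-watered phyllosphere metagenome experiments:
per-site two-group designs with 2-3 replicates, zero-inflated overdispersed
counts, heavy-tailed annotation abundances, library sizes spanning the
observed sequencing-depth classes, a configurable fraction of truly
differential annotations with known fold changes, and contaminant
annotations shared with mock/soil control samples.

Counts are simulated directly at the table level - the pipeline's entry
point - rather than via read-level simulation; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import CountTable

#: Representative per-sample sequencing depths (millions of reads), one per
#: observed depth class (small / moderate / large / deep).  Used as relative
#: library-size factors on the counts-per-megabase scale.
DEPTH_CLASS_MREADS = {"small": 0.15, "moderate": 0.35, "large": 1.0, "deep": 2.0}

#: Default experimental library sizes: each treatment group spans the
#: small-to-deep depth range (watered gets small/moderate/large, drought
#: deep/moderate/large), so normalization is exercised across the observed
#: depth spread.
_DEFAULT_LIB_CYCLE = ("small", "moderate", "large", "deep", "moderate", "large")

LABEL_NULL = "null"
LABEL_DIFFERENTIAL = "differential"
LABEL_CONTAMINANT = "contaminant"


class SimConfigError(ValueError):
    """A SimConfig field violates its contract."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated per-site experiment.

    The defaults are the package's reference study conditions: 2000
    annotations with lognormal baseline abundances, 5% truly differential
    at |log2 fold change| = 2, negative-binomial dispersion 0.2
    (variance = mu + phi*mu^2), 10% structural zeros, 50 contaminant
    annotations planted in mock/soil controls, and 3 replicates per
    treatment group with library sizes spanning the observed depth classes.
    """

    n_annotations: int = 2000
    n_per_group: int = 3
    library_sizes: tuple[float, ...] | None = None
    frac_differential: float = 0.05
    log2_fold_changes: float | tuple[float, ...] = 2.0
    dispersion: float = 0.2
    zero_inflation: float = 0.1
    n_contaminants: int = 50
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.5
    site: str = "CA"
    control_library_size: float = DEPTH_CLASS_MREADS["small"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_annotations <= 0:
            raise SimConfigError("n_annotations must be a positive integer")
        if self.n_per_group < 2:
            raise SimConfigError("n_per_group must be >= 2")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise SimConfigError("frac_differential must lie in [0, 1]")
        if self.dispersion <= 0:
            raise SimConfigError("dispersion must be > 0")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise SimConfigError("zero_inflation must lie in [0, 1)")
        if self.n_contaminants < 0:
            raise SimConfigError("n_contaminants must be >= 0")
        libs = self.resolved_library_sizes()
        if len(libs) != 2 * self.n_per_group:
            raise SimConfigError(
                f"library_sizes has {len(libs)} entries but the design has "
                f"{2 * self.n_per_group} experimental samples")
        if any(l <= 0 for l in libs):
            raise SimConfigError("all library sizes must be strictly positive")
        n_sig = self.n_differential + self.n_contaminants
        if n_sig > self.n_annotations:
            raise SimConfigError(
                "differential + contaminant annotations exceed n_annotations")

    @property
    def n_differential(self) -> int:
        return int(round(self.frac_differential * self.n_annotations))

    def resolved_library_sizes(self) -> tuple[float, ...]:
        if self.library_sizes is not None:
            return tuple(float(x) for x in self.library_sizes)
        cycle = [DEPTH_CLASS_MREADS[c] for c in _DEFAULT_LIB_CYCLE]
        n = 2 * self.n_per_group
        return tuple(cycle[i % len(cycle)] for i in range(n))

    def fold_change_pool(self) -> tuple[float, ...]:
        lfc = self.log2_fold_changes
        if np.isscalar(lfc):
            return (float(lfc), -float(lfc))
        return tuple(float(x) for x in lfc)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth labels and fold changes, aligned row-for-row with the table."""

    labels: pd.Series        # annotation_id -> null | differential | contaminant
    log2fc: pd.Series        # annotation_id -> true log2 fold change (0 for null)
    seed: int

    def ids_with_label(self, label: str) -> set[str]:
        return set(self.labels.index[self.labels == label])

    @property
    def differential_ids(self) -> set[str]:
        return self.ids_with_label(LABEL_DIFFERENTIAL)

    @property
    def contaminant_ids(self) -> set[str]:
        return self.ids_with_label(LABEL_CONTAMINANT)

    def to_records(self) -> list[dict]:
        return [
            {"annotation_id": a, "label": self.labels[a], "log2fc": float(self.log2fc[a])}
            for a in self.labels.index
        ]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Zero-safe NB(mean, phi) draw with variance mu + phi*mu^2."""
    r = 1.0 / phi
    p = r / (r + np.maximum(mean, 0.0))
    out = np.zeros_like(mean)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def generate_count_table(config: SimConfig) -> tuple[CountTable, SimTruth]:
    """Simulate one per-site count table plus its ground truth.

    Counts are zero-inflated negative binomial with per-annotation mean
    ``baseline * library_size * 2**(log2fc * treatment)``; structural zeros
    are a Bernoulli mask applied after the NB draw.  Contaminant
    annotations additionally receive counts in one mock and one soil
    control column (and behave like nulls in the experimental columns);
    all other annotations are structurally zero in the controls, mirroring
    field controls that captured only sampling-equipment and soil carryover.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_annotations
    n_per = config.n_per_group
    libs = np.asarray(config.resolved_library_sizes(), dtype=float)

    annotation_ids = [f"UPI{i:06d}" for i in range(n)]
    sample_ids = (
        [f"{config.site}_W{j+1}" for j in range(n_per)]
        + [f"{config.site}_D{j+1}" for j in range(n_per)]
    )
    treatment = np.array([0] * n_per + [1] * n_per)

    # label assignment
    perm = rng.permutation(n)
    n_diff = config.n_differential
    diff_idx = perm[:n_diff]
    cont_idx = perm[n_diff:n_diff + config.n_contaminants]
    labels = np.full(n, LABEL_NULL, dtype=object)
    labels[diff_idx] = LABEL_DIFFERENTIAL
    labels[cont_idx] = LABEL_CONTAMINANT

    lfc = np.zeros(n)
    pool = config.fold_change_pool()
    if n_diff:
        lfc[diff_idx] = rng.choice(pool, size=n_diff)

    baseline = np.exp(rng.normal(config.baseline_meanlog, config.baseline_sdlog, n))
    mu = baseline[:, None] * libs[None, :] * 2.0 ** (lfc[:, None] * treatment[None, :])
    counts = _nb_draw(rng, mu, config.dispersion)
    if config.zero_inflation > 0:
        counts[rng.random(counts.shape) < config.zero_inflation] = 0.0

    frame = pd.DataFrame(counts, index=annotation_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "site": config.site,
            "treatment": ["watered"] * n_per + ["drought"] * n_per,
            "class": "experimental",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    if config.n_contaminants > 0:
        # one mock and one soil column; contaminant rows only
        for cid, cls in ((f"mock{config.site}", "mock"), (f"soil{config.site}", "soil")):
            col = np.zeros(n)
            cont_mu = baseline[cont_idx] * config.control_library_size
            col[cont_idx] = _nb_draw(rng, cont_mu, config.dispersion)
            frame[cid] = col
            meta.loc[cid] = {"site": config.site, "treatment": "none", "class": cls}
        # guarantee every contaminant is observed in at least one control
        ctrl_cols = [f"mock{config.site}", f"soil{config.site}"]
        sub = frame.iloc[cont_idx][ctrl_cols]
        silent = sub.sum(axis=1) == 0
        if silent.any():
            frame.loc[sub.index[silent], ctrl_cols[0]] = 1.0

    table = CountTable(frame, meta)
    truth = SimTruth(
        labels=pd.Series(labels, index=annotation_ids, name="label"),
        log2fc=pd.Series(lfc, index=annotation_ids, name="log2fc"),
        seed=config.seed,
    )
    return table, truth


def generate_trait_table(
    n_per_group: int,
    effect: float,
    sd: float,
    seed: int,
    baseline: float = 1.0,
    trait_name: str = "height",
    units: str = "m",
    site: str = "CA",
    n_plots_per_group: int = 3,
    plot_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate a two-group plant-trait table with known treatment effect.

    The true watered-minus-drought difference is ``effect`` (positive =
    smaller under drought).  Observations are assigned round-robin to
    ``n_plots_per_group`` plots per treatment; ``plot_sd`` > 0 adds a
    shared normal plot effect, giving the block structure of a real field
    layout.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    plot_counter = 100
    for gi, (treat, mean) in enumerate(
        (("watered", baseline), ("drought", baseline - effect))
    ):
        plots = [plot_counter + gi * 10 + k for k in range(n_plots_per_group)]
        offsets = rng.normal(0.0, plot_sd, n_plots_per_group) if plot_sd > 0 else np.zeros(n_plots_per_group)
        for i in range(n_per_group):
            k = i % n_plots_per_group
            rows.append(
                {
                    "site": site,
                    "plot_id": plots[k],
                    "treatment": treat,
                    "trait_name": trait_name,
                    "value": rng.normal(mean + offsets[k], sd),
                    "units": units,
                }
            )
    return pd.DataFrame(rows)


def _generate_go_mapping(
    annotation_ids: list[str], rng: np.random.Generator, mean_terms: float = 1.2,
    n_terms_pool: int = 400,
) -> pd.DataFrame:
    """Many-to-many UniProt->GO mapping with unmapped IDs.

    Term counts per ID are Poisson(mean_terms), so some IDs map to several
    terms and some to none; the first two IDs are forced to 2 and 0 terms
    so both situations are always represented.
    """
    terms = [f"GO:{i:07d}" for i in range(1, n_terms_pool + 1)]
    namespaces = ("process", "function")
    pairs = []
    counts = rng.poisson(mean_terms, len(annotation_ids))
    if len(counts) >= 2:
        counts[0], counts[1] = 2, 0
    for aid, k in zip(annotation_ids, counts):
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        for t in chosen:
            pairs.append((aid, terms[t], namespaces[t % 2]))
    return pd.DataFrame(pairs, columns=["uniprot_id", "go_id", "namespace"])


def write_fixture_set(directory, config: SimConfig) -> dict:
    """Write a complete fixture set and return its manifest.

    Emits the count TSV, metadata CSV, UniProt->GO mapping TSV and truth
    JSON for one simulated experiment; the manifest records paths and the
    seed used.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table, truth = generate_count_table(config)

    counts_path = directory / "counts.tsv"
    meta_path = directory / "metadata.csv"
    mapping_path = directory / "go_mapping.tsv"
    truth_path = directory / "truth.json"

    table.write(counts_path, meta_path)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9151]))
    mapping = _generate_go_mapping(table.annotation_ids, rng)
    mapping.to_csv(mapping_path, sep="\t", index=False)
    with open(truth_path, "w") as fh:
        json.dump(truth.to_records(), fh, indent=1)

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "counts": str(counts_path),
        "metadata": str(meta_path),
        "go_mapping": str(mapping_path),
        "truth": str(truth_path),
        "n_annotations": table.n_annotations,
        "n_samples": len(table.sample_ids),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_truth(path) -> SimTruth:
    """Read a truth JSON written by :func:`write_fixture_set`."""
    with open(path) as fh:
        records = json.load(fh)
    idx = [r["annotation_id"] for r in records]
    return SimTruth(
        labels=pd.Series([r["label"] for r in records], index=idx, name="label"),
        log2fc=pd.Series([r["log2fc"] for r in records], index=idx, name="log2fc"),
        seed=-1,
    )
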