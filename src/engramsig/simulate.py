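"""Synthetic single-nucleus RNA-seq cohorts with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: cell-type marker genes, an activity response restricted to the
responsive population (dentate granule neurons by default), temporal gene
groups with early / sustained / late dynamics, and a bimodally expressed
predictive-gene set carried by Reactivated nuclei and by a "primed" subset
of single-exposure late nuclei.  Counts are drawn from a negative-binomial
model, converted to TPM (transcripts per million) and log2(TPM+1), matching
the scale of the real pipeline.  Every emitted nucleus and gene carries a
truth record, so recovery of clusters, differential expression, signatures
and reactivity can all be scored against a known answer.

Conditions follow the behavioural design: home cage (HC), one novel
environment exposure sampled 1, 4 or 5 hours later (NE1h/NE4h/NE5h), and
double exposure to the same (AA) or a different (AC) environment.  Protein
states are flow-cytometry FOS / ARC labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .gonet import GOAnnotation

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_experiment",
    "simulate_go_annotation",
    "default_nucleus_table",
    "save_simulation",
]

CONDITIONS = ("HC", "NE1h", "NE4h", "NE5h", "AA", "AC")

#: significance pattern of each temporal group across the three comparisons
#: (1 h FOS+ vs HC, 4 h ARC+FOS- vs HC, 5 h ARC+FOS- vs HC)
GROUP_PATTERNS: dict[int, frozenset[str]] = {
    1: frozenset({"1h"}),
    2: frozenset({"5h"}),
    3: frozenset({"4h"}),
    4: frozenset({"4h", "5h"}),
    5: frozenset({"1h", "4h", "5h"}),
    6: frozenset({"1h", "5h"}),
    7: frozenset({"1h", "4h"}),
}

#: a handful of genes named after their real counterparts so that Arc-based
#: rules and anchors resolve on simulated data
_NAMED_GENES = {
    1: ["Fos", "Fosb", "Egr1", "Nr4a2", "Kdm6b"],
    4: ["Sorcs3", "Dlg2", "Gabra4", "Grm7"],
    5: ["Arc", "Nptx2", "Gadd45b", "Synpo"],
}
_NAMED_PREDICTIVE = ["Blnk", "Tnik", "Acan", "Entpd4", "Hes7"]


def default_nucleus_table() -> dict[tuple[str, str, str, str], int]:
    """Default per-stratum nucleus counts, keyed (cell_type, condition, fos, arc).

    DG strata mirror the double-exposure design with hold-out-sized classes
    (15 training + test nuclei per reactivity class); CA1 and VIP carry only
    the home-cage and 1-h strata needed for the cross-cell-type comparisons.
    """
    table: dict[tuple[str, str, str, str], int] = {
        ("DG", "HC", "neg", "unknown"): 40,
        ("DG", "NE1h", "pos", "unknown"): 30,
        ("DG", "NE1h", "neg", "unknown"): 30,
        ("DG", "NE4h", "neg", "pos"): 30,
        ("DG", "NE5h", "neg", "pos"): 30,
        ("DG", "AA", "pos", "pos"): 88,
        ("DG", "AA", "neg", "pos"): 65,
        ("DG", "AC", "pos", "pos"): 30,
        ("DG", "AC", "neg", "pos"): 30,
    }
    for ct in ("CA1", "VIP"):
        table[(ct, "HC", "neg", "unknown")] = 15
        table[(ct, "NE1h", "pos", "unknown")] = 15
        table[(ct, "NE1h", "neg", "unknown")] = 15
    return table


@dataclass
class SimulationConfig:
    """Parameters of a simulated cohort.

    ``effect_size`` is the mean log2 shift applied to induced genes (so a
    value of 2 quadruples the expected count); ``reactivated_fraction``
    controls both the share of double-exposure ARC+FOS+ nuclei that are
    Reactivated and the share of single-exposure late nuclei that carry the
    primed predictive signature.  ``nb_dispersion`` is the negative-binomial
    dispersion (variance = mu + dispersion * mu^2); 0 gives Poisson counts.
    Dropout is Bernoulli zeroing after the count draw with an
    expression-dependent rate, dropout_rate * exp(-mu / dropout_decay), so
    lowly expressed transcripts drop out often and deeply covered ones
    almost never do — the pattern seen in deep-coverage SmartSeq2 nuclei.
    ``reactivated_late_boost`` adds extra log2 units to sustained/late genes
    in Reactivated nuclei, reflecting the renewed late program after a second
    activation.
    """

    n_genes: int = 2000
    n_nuclei: Mapping[tuple[str, str, str, str], int] = field(
        default_factory=default_nucleus_table
    )
    marker_genes_per_type: int = 30
    temporal_group_sizes: Mapping[int, int] = field(
        default_factory=lambda: {1: 252, 2: 20, 3: 20, 4: 129, 5: 107, 6: 20, 7: 20}
    )
    effect_size: float = 2.0
    marker_effect_size: float = 3.0
    predictive_gene_count: int = 60
    reactivated_fraction: float = 0.41
    dropout_rate: float = 0.2
    dropout_decay: float = 10.0
    nb_dispersion: float = 0.3
    batch_count: int = 2
    batch_effect_sd: float = 0.15
    baseline_mean_range: tuple[float, float] = (1.0, 100.0)
    ballast_genes: int = 100
    ballast_mean_range: tuple[float, float] = (500.0, 2000.0)
    seed: int = 0
    gene_seed: int | None = None
    # secondary knobs (held at realistic values; not part of the main sweep)
    response_cell_types: tuple[str, ...] = ("DG",)
    down_fraction: float = 0.2
    reactivated_late_boost: float = 1.0
    predictive_up_fraction: float = 0.7
    predictive_high_mean: float = 25.0
    predictive_low_mean: float = 0.1
    predictive_on_prob: float = 0.9
    predictive_off_prob: float = 0.05
    arc_baseline_mean: float = 1.0
    fos_low_effect_scale: float = 0.5
    mice_per_condition: int = 3
    reads_per_count: int = 10

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(v < 0 for v in self.n_nuclei.values()):
            raise ValueError("nucleus counts must be non-negative")
        for key in self.n_nuclei:
            if key[1] not in CONDITIONS:
                raise ValueError(f"unknown condition in nucleus table: {key[1]}")
        if any(v < 0 for v in self.temporal_group_sizes.values()):
            raise ValueError("temporal group sizes must be non-negative")
        if not set(self.temporal_group_sizes) <= set(GROUP_PATTERNS):
            raise ValueError("temporal group keys must be in 1..7")
        for frac in (self.reactivated_fraction, self.dropout_rate, self.down_fraction,
                     self.predictive_up_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.batch_count <= 0:
            raise ValueError("batch_count must be positive")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ValueError("baseline_mean_range must be positive and ordered")
        n_structured = (
            sum(self.temporal_group_sizes.values())
            + self.marker_genes_per_type * len(self.cell_types)
            + self.predictive_gene_count
            + self.ballast_genes
        )
        if n_structured > self.n_genes:
            raise ValueError(
                f"structured genes ({n_structured}) exceed n_genes ({self.n_genes})"
            )

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(sorted({k[0] for k in self.n_nuclei}))

    # -- structured-text round trip -------------------------------------
    def to_yaml(self) -> str:
        d = self.__dict__.copy()
        d["n_nuclei"] = {"|".join(k): int(v) for k, v in self.n_nuclei.items()}
        d["temporal_group_sizes"] = {int(k): int(v) for k, v in self.temporal_group_sizes.items()}
        d["baseline_mean_range"] = list(self.baseline_mean_range)
        d["ballast_mean_range"] = list(self.ballast_mean_range)
        d["response_cell_types"] = list(self.response_cell_types)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        d["n_nuclei"] = {tuple(k.split("|")): int(v) for k, v in d["n_nuclei"].items()}
        d["temporal_group_sizes"] = {int(k): int(v) for k, v in d["temporal_group_sizes"].items()}
        d["baseline_mean_range"] = tuple(d["baseline_mean_range"])
        d["ballast_mean_range"] = tuple(d["ballast_mean_range"])
        d["response_cell_types"] = tuple(d["response_cell_types"])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth for a simulated cohort.

    ``nucleus_truth`` has one row per nucleus (cell_type, condition,
    activity_state in {baseline, early, late, reactivated}, primed flag,
    batch); ``gene_truth`` one row per gene (temporal_group 0 = none,
    marker_of, predictive flag, direction).  ``counts`` are the raw
    negative-binomial counts before TPM conversion.
    """

    nucleus_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    counts: pd.DataFrame


def _gene_names(prefix_named: list[str], n: int, offset: int) -> list[str]:
    names = list(prefix_named[:n])
    names += [f"g{offset + i:05d}" for i in range(n - len(names))]
    return names


def _build_gene_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows: list[dict] = []
    offset = 0
    for group, size in sorted(config.temporal_group_sizes.items()):
        named = _NAMED_GENES.get(group, [])
        for name in _gene_names(named, size, offset):
            direction = "down" if rng.random() < config.down_fraction else "up"
            rows.append(dict(gene=name, temporal_group=group, marker_of="none",
                             predictive=False, direction=direction))
        offset += size
    for ct in config.cell_types:
        for i in range(config.marker_genes_per_type):
            rows.append(dict(gene=f"mk_{ct}_{i:03d}", temporal_group=0,
                             marker_of=ct, predictive=False, direction="up"))
    n_pred = config.predictive_gene_count
    for name in _gene_names(_NAMED_PREDICTIVE, n_pred, offset):
        direction = "up" if rng.random() < config.predictive_up_fraction else "down"
        rows.append(dict(gene=name, temporal_group=0, marker_of="none",
                         predictive=True, direction=direction))
    for i in range(config.ballast_genes):
        # high-expression housekeeping-like transcripts that carry most of
        # the library mass, as in real nuclei; they stabilize TPM scaling
        rows.append(dict(gene=f"hk{i:04d}", temporal_group=0, marker_of="none",
                         predictive=False, direction="none", ballast=True))
    n_bg = config.n_genes - len(rows)
    for i in range(n_bg):
        rows.append(dict(gene=f"bg{i:05d}", temporal_group=0, marker_of="none",
                         predictive=False, direction="none"))
    truth = pd.DataFrame(rows).set_index("gene")
    if "ballast" not in truth.columns:
        truth["ballast"] = False
    truth["ballast"] = truth["ballast"].astype(object).eq(True)
    if truth.index.duplicated().any():
        raise ValueError("internal error: duplicate simulated gene names")
    return truth


def _build_nucleus_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows: list[dict] = []
    i = 0
    for (ct, cond, fos, arc), n in sorted(config.n_nuclei.items()):
        for _ in range(n):
            state, primed = "baseline", False
            if cond == "NE1h":
                state = "early" if fos in ("pos", "low") else "baseline"
            elif cond in ("NE4h", "NE5h"):
                if arc == "pos" and fos != "pos":
                    state = "late"
                    primed = bool(rng.random() < config.reactivated_fraction)
                elif fos == "pos":
                    state = "early"
            elif cond in ("AA", "AC"):
                if fos == "pos" and arc == "pos":
                    if cond == "AA" and rng.random() < config.reactivated_fraction:
                        state = "reactivated"
                    else:
                        state = "early"
                elif arc == "pos":
                    state = "late"
            rows.append(dict(
                nucleus_id=f"n{i:05d}", cell_type=ct, condition=cond,
                fos_protein=fos, arc_protein=arc, activity_state=state,
                primed=primed,
                batch=int(rng.integers(config.batch_count)),
                mouse_id=f"{cond}_m{int(rng.integers(config.mice_per_condition)) + 1}",
            ))
            i += 1
    return pd.DataFrame(rows).set_index("nucleus_id")


def _activity_profile(row: pd.Series) -> frozenset[str]:
    """Which of the three reference comparisons a nucleus's state activates."""
    state, cond = row["activity_state"], row["condition"]
    if state == "early":
        return frozenset({"1h"})
    if state == "late":
        return frozenset({"4h"}) if cond == "NE4h" else frozenset({"5h"})
    if state == "reactivated":
        return frozenset({"1h", "5h"})
    return frozenset()


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Draw one cohort: (log2(TPM+1) matrix, metadata, truth).

    Identical config + seed reproduces the output bit-for-bit.  The returned
    matrix is genes x nuclei; metadata carries condition, population, FOS/ARC
    protein status, mouse, batch, total aligned reads and detected genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    # gene-level biology (roles, directions, baseline abundances) is a
    # property of the genome, not of the sampled animals: a second cohort
    # simulated with the same gene_seed shares it while resampling nuclei
    rng_genes = np.random.default_rng(
        config.seed if config.gene_seed is None else config.gene_seed)

    gene_truth = _build_gene_truth(config, rng_genes)
    nucleus_truth = _build_nucleus_truth(config, rng)
    genes = gene_truth.index.to_numpy()
    nuclei = nucleus_truth.index.to_numpy()
    G, N = len(genes), len(nuclei)

    lo, hi = config.baseline_mean_range
    base_mu = np.exp(rng_genes.uniform(np.log(lo), np.log(hi), size=G))
    is_ballast = gene_truth["ballast"].to_numpy(dtype=bool)
    if is_ballast.any():
        blo, bhi = config.ballast_mean_range
        base_mu[is_ballast] = np.exp(
            rng_genes.uniform(np.log(blo), np.log(bhi), size=int(is_ballast.sum())))
    is_pred = gene_truth["predictive"].to_numpy()
    pred_up = is_pred & (gene_truth["direction"] == "up").to_numpy()
    pred_down = is_pred & (gene_truth["direction"] == "down").to_numpy()
    base_mu[pred_up] = config.predictive_low_mean
    base_mu[pred_down] = config.predictive_high_mean
    if "Arc" in gene_truth.index:
        # the FOS-/Arc-high discordance rule presupposes a low Arc baseline
        # in inactive nuclei; pin it so that premise holds in simulation
        base_mu[gene_truth.index.get_loc("Arc")] = config.arc_baseline_mean
    gene_truth = gene_truth.assign(base_mean=base_mu)

    batch_shift = rng.normal(0.0, config.batch_effect_sd,
                             size=(config.batch_count, G))

    group = gene_truth["temporal_group"].to_numpy()
    direction_up = (gene_truth["direction"] == "up").to_numpy()
    marker_of = gene_truth["marker_of"].to_numpy()
    patterns = {g: GROUP_PATTERNS[g] for g in GROUP_PATTERNS}
    late_ish = np.array([
        g > 0 and bool(patterns[g] & {"4h", "5h"}) for g in group
    ])

    mu = np.empty((G, N))
    eff = config.effect_size
    for j, (nid, row) in enumerate(nucleus_truth.iterrows()):
        m = base_mu.copy()
        ct = row["cell_type"]
        # cell identity dominates the transcriptome: markers shift harder
        # than activity-response genes
        m[marker_of == ct] *= 2.0 ** config.marker_effect_size
        responsive = ct in config.response_cell_types
        if responsive and row["activity_state"] != "baseline":
            profile = _activity_profile(row)
            scale = config.fos_low_effect_scale if row["fos_protein"] == "low" else 1.0
            active = np.array([
                g > 0 and bool(patterns[g] & profile) for g in group
            ])
            shift = np.where(direction_up, eff, -eff) * scale
            if row["activity_state"] == "reactivated":
                shift = shift + np.where(
                    direction_up, config.reactivated_late_boost,
                    -config.reactivated_late_boost) * late_ish
            m[active] *= 2.0 ** shift[active]
        if responsive:
            # per-gene penetrance of the predictive program: even in carrier
            # nuclei each gene is on only with probability predictive_on_prob,
            # so no single gene separates the classes on its own
            carrier = row["activity_state"] == "reactivated" or row["primed"]
            p_on = config.predictive_on_prob if carrier else config.predictive_off_prob
            flip = rng.random(G) < p_on
            m[pred_up & flip] = config.predictive_high_mean
            m[pred_down & flip] = config.predictive_low_mean
        m *= 2.0 ** batch_shift[row["batch"]]
        mu[:, j] = m

    counts = _nb_counts(mu, config.nb_dispersion, rng)
    if config.dropout_rate > 0:
        # expression-dependent Bernoulli zeroing: capture failures hit
        # low-expressed genes hard and deeply sequenced transcripts rarely
        p_drop = config.dropout_rate * np.exp(-mu / config.dropout_decay)
        keep = rng.random(counts.shape) >= p_drop
        counts = counts * keep
    counts = counts.astype(np.int64)

    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("simulated nucleus with empty library; increase means")
    tpm = counts / lib * 1e6
    matrix = pd.DataFrame(np.log2(tpm + 1.0), index=genes, columns=nuclei)
    counts_df = pd.DataFrame(counts, index=genes, columns=nuclei)

    metadata = pd.DataFrame({
        "condition": nucleus_truth["condition"],
        "population": nucleus_truth["cell_type"],
        "fos_protein": nucleus_truth["fos_protein"],
        "arc_protein": nucleus_truth["arc_protein"],
        "mouse_id": nucleus_truth["mouse_id"],
        "batch_id": nucleus_truth["batch"].map(lambda b: f"b{b}"),
        "total_aligned_reads": lib * config.reads_per_count,
        "detected_genes": (matrix.to_numpy() > 1.0).sum(axis=0),
    }, index=nucleus_truth.index)

    truth = SimulationTruth(nucleus_truth=nucleus_truth, gene_truth=gene_truth,
                            counts=counts_df)
    return matrix, metadata, truth


def simulate_go_annotation(
    n_genes: int,
    n_terms: int,
    max_parents: int = 8,
    seed: int = 0,
    genes: list[str] | None = None,
    mean_terms_per_gene: float = 2.0,
    min_parents: int = 0,
) -> GOAnnotation:
    """Random gene→term annotation with per-term parent counts.

    Every gene receives at least one term; parent counts are uniform on
    [min_parents, max_parents] (set ``min_parents=1`` to exclude root-like
    zero-parent terms, which carry zero weight under the default distance
    weighting).  Deterministic given ``seed``.
    """
    if n_genes <= 0 or n_terms <= 0 or max_parents < 0:
        raise ValueError("n_genes and n_terms must be positive, max_parents >= 0")
    if not 0 <= min_parents <= max_parents:
        raise ValueError("min_parents must be in [0, max_parents]")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"g{i:05d}" for i in range(n_genes)]
    elif len(genes) != n_genes:
        raise ValueError("genes list length must equal n_genes")
    terms = [f"T{i:04d}" for i in range(n_terms)]
    gene_terms = {}
    for g in genes:
        k = 1 + rng.poisson(max(mean_terms_per_gene - 1.0, 0.0))
        k = min(int(k), n_terms)
        chosen = rng.choice(n_terms, size=k, replace=False)
        gene_terms[g] = frozenset(terms[i] for i in chosen)
    parent_count = {t: int(rng.integers(min_parents, max_parents + 1)) for t in terms}
    return GOAnnotation(gene_terms, parent_count)


def save_simulation(
    out_dir: str | Path,
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
    format: str = "tsv",
) -> None:
    """Write matrix, metadata, truth tables and the config to a directory."""
    from .io import write_matrix  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if format == "tsv" else "mtx"
    write_matrix(matrix, out / f"matrix.{ext}", format=format)
    metadata.to_csv(out / "metadata.tsv", sep="\t")
    truth.nucleus_truth.to_csv(out / "nucleus_truth.tsv", sep="\t")
    truth.gene_truth.to_csv(out / "gene_truth.tsv", sep="\t",
                            float_format="%.10g")
    (out / "config.yaml").write_text(config.to_yaml())
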