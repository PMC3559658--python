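"""Synthetic matched copy-number/expression cohorts with known ground truth.

The generator instantiates exactly the data model the analysis assumes:
segmental copy-number events on a probe grid, a log-linear cis coupling
e = a + b*c + eps between each gene's copy number and its expression,
co-occurring-aberration confounding (several genes sharing one amplicon),
and planted in-trans modules whose member genes track a driver gene's
expression deviation.  A gene-set collection embedding each module among
size-matched decoy sets makes end-to-end recovery and specificity testable
without any external data.

Default condition (the benchmark cohort): 3000 genes on 10 chromosomes,
100 samples, one driver amplicon of 11 genes (1 driver + 10 passengers,
single-copy gain of log2(3/2) ~ 0.58 in 30% of samples), cis slope 1.0
everywhere, one 50-gene module coupled to the driver at 0.7, and 500 decoy
sets of 50 genes.  Noise levels (copy-number probe sd 0.15, expression sd
0.25, module-member sd 0.25) are typical of array data after normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GeneSetCollection, GeneTable, GenomicMatrix

logger = logging.getLogger("ipac.synthdata")


@dataclass(frozen=True)
class AberrationEvent:
    """One segmental event: log2 ``magnitude`` added to CN probes in
    [start, end] on ``chromosome`` for a ``fraction`` of samples."""

    chromosome: str
    start: int
    end: int
    magnitude: float
    fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("affected fraction must be in (0, 1]")
        if self.end < self.start or self.start < 1:
            raise ValueError("invalid event interval")


@dataclass(frozen=True)
class TransModule:
    """A planted in-trans module: ``members`` add ``coupling`` times the
    driver's expression deviation to their own expression."""

    driver: str
    members: tuple[str, ...]
    coupling: float
    member_noise_sd: float | None = None   # None: use spec.expr_noise_sd

    def __post_init__(self) -> None:
        if self.driver in self.members:
            raise ValueError("module members must be disjoint from the driver")


@dataclass
class CohortSpec:
    """Layout, events, cis coupling and modules of a synthetic cohort."""

    n_genes: int = 3000
    n_samples: int = 100
    n_chromosomes: int = 10
    gene_spacing: int = 100_000          # bp between genes on a chromosome
    cn_probe_offset: int = 500           # CN probe sits this far below the gene
    cn_noise_sd: float = 0.15
    expr_noise_sd: float = 0.25
    default_slope: float = 1.0           # b_g of the cis model
    default_intercept: float = 0.0       # a_g
    slopes: dict[str, float] = field(default_factory=dict)       # overrides
    intercepts: dict[str, float] = field(default_factory=dict)
    events: list[AberrationEvent] = field(default_factory=list)
    modules: list[TransModule] = field(default_factory=list)
    n_decoy_sets: int = 0
    decoy_set_size: int = 50

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def layout(self) -> pd.DataFrame:
        """Gene -> (chromosome, position); genes split evenly, round-robin
        blocks, positions on a regular grid."""
        genes = self.gene_names()
        per_chrom = int(np.ceil(self.n_genes / self.n_chromosomes))
        chroms, pos = [], []
        for i in range(self.n_genes):
            chroms.append(f"chr{i // per_chrom + 1}")
            pos.append((i % per_chrom + 1) * self.gene_spacing)
        return pd.DataFrame({"chromosome": chroms, "position": pos},
                            index=pd.Index(genes, name="gene_symbol"))

    def validate(self) -> None:
        layout = self.layout()
        chrom_max = layout.groupby("chromosome")["position"].max()
        intervals: dict[str, list[tuple[int, int, float]]] = {}
        for ev in self.events:
            if ev.chromosome not in chrom_max.index:
                raise ValueError(f"event on unknown chromosome {ev.chromosome}")
            if ev.end > chrom_max[ev.chromosome] + self.gene_spacing:
                raise ValueError("event extends beyond chromosome bounds")
            for (s, e, m) in intervals.get(ev.chromosome, []):
                if ev.start <= e and s <= ev.end and m != ev.magnitude:
                    raise ValueError("overlapping events with conflicting "
                                     f"magnitudes on {ev.chromosome}")
            intervals.setdefault(ev.chromosome, []).append(
                (ev.start, ev.end, ev.magnitude))
        genes = set(layout.index)
        drivers = {m.driver for m in self.modules}
        for mod in self.modules:
            if mod.driver not in genes:
                raise ValueError(f"unknown driver {mod.driver}")
            unknown = set(mod.members) - genes
            if unknown:
                raise ValueError(f"unknown module members {sorted(unknown)[:3]}")
            if drivers & set(mod.members):
                raise ValueError("a driver cannot be a member of a module")


@dataclass
class SyntheticCohort:
    """Generated cohort plus every piece of planted ground truth."""

    cn: GenomicMatrix                  # probe-level noisy copy number
    expr: GenomicMatrix                # probe-level expression
    sets: GeneSetCollection
    true_segment_values: pd.DataFrame  # genes x samples, noise-free CN
    truth: dict[str, pd.DataFrame]     # events, affected samples, drivers, modules
    spec: CohortSpec
    seed: int


def _affected_samples(rng: np.random.Generator, n_samples: int,
                      fraction: float) -> np.ndarray:
    """Exactly round(fraction * n) distinct samples, chosen without
    replacement."""
    k = int(round(fraction * n_samples))
    return np.sort(rng.choice(n_samples, size=k, replace=False))


def generate_cohort(spec: CohortSpec, seed: int = 0) -> SyntheticCohort:
    """Generate matched probe-level CN and expression tracks plus gene sets.

    Copy number is baseline 0 plus event magnitudes for affected samples plus
    Gaussian probe noise; expression of gene g is
    a_g + b_g * (true segment value) + coupling * (driver deviation, for
    module members) + Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    layout = spec.layout()
    genes = list(layout.index)
    samples = [f"S{i:03d}" for i in range(1, spec.n_samples + 1)]
    n_g, n_s = spec.n_genes, spec.n_samples

    # noise-free per-gene copy number (the "true segment value")
    true_cn = np.zeros((n_g, n_s))
    event_rows, affected_rows = [], []
    for ei, ev in enumerate(spec.events):
        on_chrom = layout["chromosome"] == ev.chromosome
        in_span = on_chrom & layout["position"].between(ev.start, ev.end)
        gidx = np.flatnonzero(in_span.to_numpy())
        affected = _affected_samples(rng, n_s, ev.fraction)
        true_cn[np.ix_(gidx, affected)] += ev.magnitude
        event_rows.append((ei, ev.chromosome, ev.start, ev.end, ev.magnitude,
                           ev.fraction, len(gidx)))
        affected_rows.extend((ei, samples[s]) for s in affected)

    slopes = np.array([spec.slopes.get(g, spec.default_slope) for g in genes])
    intercepts = np.array([spec.intercepts.get(g, spec.default_intercept)
                           for g in genes])
    expr = (intercepts[:, None] + slopes[:, None] * true_cn
            + rng.normal(0.0, spec.expr_noise_sd, size=(n_g, n_s)))

    # module members track the driver's expression deviation
    gene_idx = {g: i for i, g in enumerate(genes)}
    module_rows = []
    for mod in spec.modules:
        d = gene_idx[mod.driver]
        deviation = expr[d] - expr[d].mean()
        sd = (spec.expr_noise_sd if mod.member_noise_sd is None
              else mod.member_noise_sd)
        for m in mod.members:
            j = gene_idx[m]
            expr[j] = (intercepts[j] + slopes[j] * true_cn[j]
                       + mod.coupling * deviation + rng.normal(0.0, sd, n_s))
            module_rows.append((mod.driver, m, mod.coupling))

    cn_values = true_cn + rng.normal(0.0, spec.cn_noise_sd, size=(n_g, n_s))

    # probe tracks: one expression probe per gene at the gene position and
    # one CN probe slightly offset (so nearest-probe matching is exercised)
    cn_pos = np.maximum(layout["position"].to_numpy() - spec.cn_probe_offset, 1)
    cn_ann = pd.DataFrame({"chromosome": layout["chromosome"].to_numpy(),
                           "position": cn_pos},
                          index=pd.Index([f"cnp_{g}" for g in genes],
                                         name="probe_id"))
    cn_gm = GenomicMatrix(values=pd.DataFrame(cn_values, index=cn_ann.index,
                                              columns=samples),
                          annotations=cn_ann, kind="copy_number")
    expr_ann = pd.DataFrame({"gene_symbol": genes,
                             "chromosome": layout["chromosome"].to_numpy(),
                             "position": layout["position"].to_numpy()},
                            index=pd.Index([f"exp_{g}" for g in genes],
                                           name="probe_id"))
    expr_gm = GenomicMatrix(values=pd.DataFrame(expr, index=expr_ann.index,
                                                columns=samples),
                            annotations=expr_ann, kind="expression")

    # gene sets: one per module plus size-matched decoys from non-module genes
    sets = GeneSetCollection()
    module_genes: set[str] = set()
    for mi, mod in enumerate(spec.modules, start=1):
        sets.add(f"MODULE_{mi:02d}", f"planted module of {mod.driver}",
                 mod.members)
        module_genes.update(mod.members)
        module_genes.add(mod.driver)
    eligible = np.array(sorted(set(genes) - module_genes))
    width = len(str(max(spec.n_decoy_sets, 1)))
    for k in range(1, spec.n_decoy_sets + 1):
        decoy = rng.choice(eligible, size=spec.decoy_set_size, replace=False)
        sets.add(f"DECOY_{k:0{width}d}", "decoy set", decoy)

    truth = {
        "events": pd.DataFrame(event_rows, columns=[
            "event", "chromosome", "start", "end", "magnitude", "fraction",
            "n_genes"]),
        "affected": pd.DataFrame(affected_rows, columns=["event", "sample"]),
        "drivers": pd.DataFrame(
            [(m.driver, spec.slopes.get(m.driver, spec.default_slope),
              spec.intercepts.get(m.driver, spec.default_intercept))
             for m in spec.modules],
            columns=["gene", "slope", "intercept"]),
        "modules": pd.DataFrame(module_rows,
                                columns=["driver", "member", "coupling"]),
    }
    return SyntheticCohort(cn=cn_gm, expr=expr_gm, sets=sets,
                           true_segment_values=pd.DataFrame(
                               true_cn, index=pd.Index(genes,
                                                       name="gene_symbol"),
                               columns=samples),
                           truth=truth, spec=spec, seed=seed)


def benchmark_spec(n_genes: int = 3000, n_samples: int = 100,
                   n_decoy_sets: int = 500, module_size: int = 50,
                   amplicon_genes: int = 11, event_fraction: float = 0.3,
                   event_magnitude: float = 0.58, coupling: float = 0.7,
                   seed: int = 0) -> CohortSpec:
    """The default benchmark cohort: one driver amplicon plus one module.

    The amplicon covers ``amplicon_genes`` consecutive genes on chr1 (driver
    in the middle, the rest passengers); the module members are spread over
    the other chromosomes.  Module membership is chosen with a generator
    seeded separately from the cohort noise so the same truth layout can be
    generated under many noise seeds.
    """
    spec = CohortSpec(n_genes=n_genes, n_samples=n_samples,
                      n_decoy_sets=n_decoy_sets, decoy_set_size=module_size)
    layout = spec.layout()
    genes = list(layout.index)
    per_chrom = int(np.ceil(n_genes / spec.n_chromosomes))
    start_i = 100 if per_chrom > 100 + amplicon_genes else 0
    amplicon = genes[start_i:start_i + amplicon_genes]
    driver = amplicon[amplicon_genes // 2]
    ev = AberrationEvent(chromosome="chr1",
                         start=int(layout.loc[amplicon[0], "position"]),
                         end=int(layout.loc[amplicon[-1], "position"]),
                         magnitude=event_magnitude, fraction=event_fraction)
    rng = np.random.default_rng(seed + 10_000)
    off_chrom = [g for g in genes
                 if layout.loc[g, "chromosome"] != "chr1"]
    members = tuple(sorted(rng.choice(off_chrom, size=module_size,
                                      replace=False)))
    spec.events = [ev]
    spec.modules = [TransModule(driver=driver, members=members,
                                coupling=coupling)]
    return spec


def co_amplicon_fixture(n_samples: int = 100, event_fraction: float = 0.4,
                        magnitude: float = 1.0, noise_sd: float = 0.3,
                        seed: int = 0) -> GeneTable:
    """Two genes sharing one copy-number event; their expression noise is
    independent by construction.

    Models the co-occurring-aberration confounder: both genes' expressions
    track the shared copy number (cis slope 1), so they correlate in trans
    although neither influences the other.  Copy number is returned noise
    free, so the cis-model residuals are exactly event-independent.
    """
    rng = np.random.default_rng(seed)
    affected = _affected_samples(rng, n_samples, event_fraction)
    c = np.zeros(n_samples)
    c[affected] = magnitude
    e1 = c + rng.normal(0.0, noise_sd, n_samples)
    e2 = c + rng.normal(0.0, noise_sd, n_samples)
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    index = pd.Index(["GA", "GB"], name="gene_symbol")
    ann = pd.DataFrame({"chromosome": ["chr1", "chr1"],
                        "position": [1.0e6, 1.5e6]}, index=index)
    return GeneTable(cn=pd.DataFrame([c, c], index=index, columns=samples),
                     expr=pd.DataFrame([e1, e2], index=index, columns=samples),
                     annotations=ann)
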