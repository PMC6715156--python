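"""Synthetic Diversity Outbred (DO) genomes, covariates and traits.

The generator emulates the statistical structure of a DO mapping study:
8-founder mosaic genomes with Poisson-process recombination blocks, polygenic
covariance induced by realized kinship, sparse over-dispersed microbial
counts with controllable prevalence, log-normal metabolite peak areas with an
internal-standard channel, and microbe-metabolite trait pairs generated under
known causal architectures (pleiotropic, linked, causal, reactive,
independent).  Ground truth is retained so downstream recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

#: Fixed founder letter order; letters map to the eight DO founder strains
#: A/J, C57BL/6J, 129S1/SvImJ, NOD/ShiLtJ, NZO/HlLtJ, CAST/EiJ, PWK/PhJ, WSB/EiJ.
FOUNDERS = ["A", "B", "C", "D", "E", "F", "G", "H"]

FOUNDER_STRAINS = {
    "A": "A/J",
    "B": "C57BL/6J",
    "C": "129S1/SvImJ",
    "D": "NOD/ShiLtJ",
    "E": "NZO/HlLtJ",
    "F": "CAST/EiJ",
    "G": "PWK/PhJ",
    "H": "WSB/EiJ",
}


@dataclass
class GeneticMap:
    """Marker map: positions in cM and Mbp, grouped by chromosome.

    ``markers`` is indexed by marker id with columns ``chromosome``,
    ``pos_cM`` and ``pos_Mbp``; positions are strictly increasing within a
    chromosome.
    """

    markers: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "pos_cM", "pos_Mbp"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"map is missing columns {required - set(self.markers.columns)}")
        if self.markers.index.duplicated().any():
            raise ValueError("marker ids must be unique")
        for chrom, sub in self.markers.groupby("chromosome", sort=False):
            for col in ("pos_cM", "pos_Mbp"):
                if not np.all(np.diff(sub[col].to_numpy()) > 0):
                    raise ValueError(f"{col} not strictly increasing on chromosome {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.markers["chromosome"]))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Integer marker indices belonging to one chromosome."""
        return np.flatnonzero((self.markers["chromosome"] == chrom).to_numpy())

    def marker_index(self, marker_id: str) -> int:
        return int(self.markers.index.get_loc(marker_id))


@dataclass
class FounderDosage:
    """Expected founder-allele counts: individuals x markers x 8 founders.

    Every (individual, marker) slice sums to 2 (a diploid carries two founder
    haplotypes); entries lie in [0, 2].
    """

    individuals: list[str]
    markers: list[str]
    dosage: np.ndarray
    founders: list[str] = field(default_factory=lambda: list(FOUNDERS))

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m, f = self.dosage.shape
        if (n, m, f) != (len(self.individuals), len(self.markers), len(self.founders)):
            raise ValueError("dosage shape does not match id lists")
        if self.dosage.min() < -1e-12 or self.dosage.max() > 2 + 1e-12:
            raise ValueError("dosage entries must lie in [0, 2]")
        sums = self.dosage.sum(axis=2)
        if np.abs(sums - 2.0).max() > 1e-8:
            raise ValueError("each (individual, marker) dosage slice must sum to 2")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def simulate_map(
    n_chromosomes: int,
    markers_per_chr: int,
    chr_length_cM: float,
    cM_per_Mbp: float = 2.0,
    seed: int | None = None,
) -> GeneticMap:
    """Evenly spaced marker grid over ``n_chromosomes`` autosomes.

    Markers sit at ``linspace(0, chr_length_cM, markers_per_chr)``;
    physical positions follow a constant recombination rate
    ``pos_Mbp = pos_cM / cM_per_Mbp``.  Deterministic (the ``seed`` argument
    is accepted for interface uniformity).
    """
    if markers_per_chr < 2:
        raise ValueError("need at least 2 markers per chromosome")
    if chr_length_cM <= 0 or cM_per_Mbp <= 0 or n_chromosomes < 1:
        raise ValueError("chromosome count and lengths must be positive")
    rows = []
    for c in range(n_chromosomes):
        chrom = str(c + 1)
        cm = np.linspace(0.0, chr_length_cM, markers_per_chr)
        for i, p in enumerate(cm):
            rows.append((f"c{chrom}_m{i}", chrom, p, p / cM_per_Mbp))
    df = pd.DataFrame(rows, columns=["marker", "chromosome", "pos_cM", "pos_Mbp"])
    return GeneticMap(df.set_index("marker"))


def _mosaic_haplotype(length_cM: float, density: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: breakpoints (sorted, cM) and founder labels per segment.

    Founder switches form a homogeneous Poisson process with rate ``density``
    per cM; after a switch the new founder is drawn uniformly from the other
    seven, so every breakpoint is a real block boundary.
    """
    k = rng.poisson(density * length_cM)
    breaks = np.sort(rng.uniform(0.0, length_cM, size=k))
    labels = np.empty(k + 1, dtype=np.int64)
    labels[0] = rng.integers(8)
    for i in range(1, k + 1):
        step = rng.integers(1, 8)  # uniform over the other 7 founders
        labels[i] = (labels[i - 1] + step) % 8
    return breaks, labels


def simulate_do_genomes(
    gmap: GeneticMap,
    n_individuals: int,
    switch_density_per_cM: float = 0.2,
    seed: int | None = None,
    smoothing_weight: float = 0.0,
    dirichlet_alpha: float = 1.0,
) -> FounderDosage:
    """DO-style founder mosaic genomes as dosage arrays.

    Each individual carries two independent founder mosaics per chromosome;
    dosage at a marker is the sum of the two haplotype indicators.  The
    default switch density (0.2 per cM per chromosome pair, i.e. 0.1 per
    gamete) approximates the block structure after ~20 outbreeding
    generations.  ``smoothing_weight`` > 0 mixes each dosage slice with a
    Dirichlet draw (scaled to sum 2), emulating haplotype-reconstruction
    uncertainty; slices still sum to 2 exactly.
    """
    if gmap.n_markers == 0:
        raise ValueError("empty map")
    if switch_density_per_cM < 0:
        raise ValueError("switch density must be non-negative")
    if not (0.0 <= smoothing_weight < 1.0):
        raise ValueError("smoothing weight must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n, m = n_individuals, gmap.n_markers
    dosage = np.zeros((n, m, 8))
    gamete_density = switch_density_per_cM / 2.0
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_slice(chrom)
        pos = gmap.markers["pos_cM"].to_numpy()[idx]
        length = float(pos[-1]) if len(pos) else 0.0
        for i in range(n):
            for _hap in range(2):
                breaks, labels = _mosaic_haplotype(length, gamete_density, rng)
                seg = np.searchsorted(breaks, pos, side="right")
                dosage[i, idx, labels[seg]] += 1.0
    if smoothing_weight > 0.0:
        noise = rng.dirichlet(np.full(8, dirichlet_alpha), size=(n, m)) * 2.0
        dosage = (1.0 - smoothing_weight) * dosage + smoothing_weight * noise
    individuals = [f"DO{i + 1:04d}" for i in range(n)]
    return FounderDosage(individuals, list(gmap.markers.index), dosage)


def simulate_covariates(
    individuals: list[str],
    seed: int | None = None,
    n_waves: int = 5,
) -> pd.DataFrame:
    """Sex (0/1), experimental wave (1..n_waves) and days on diet per mouse.

    Days on diet are uniform integers over 147-175 (21-25 weeks).
    """
    if n_waves > 5:
        raise ValueError("at most 5 waves")
    rng = np.random.default_rng(seed)
    n = len(individuals)
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "wave": rng.integers(1, n_waves + 1, size=n),
            "days_on_diet": rng.integers(147, 176, size=n),
        },
        index=pd.Index(individuals, name="individual"),
    )


# ---------------------------------------------------------------------------
# Trait generation
# ---------------------------------------------------------------------------

ARCHITECTURES = ("pleiotropic", "linked", "causal", "reactive", "independent")


@dataclass
class TraitSpec:
    """Generating model for one trait.

    qtl_var is the fraction of the trait's non-covariate variance explained
    by the QTL; h2 is the polygenic fraction of the remaining variance.
    Founder effects are centered to mean zero by convention; if omitted, a
    random centered 8-vector is drawn.
    """

    name: str
    trait_class: str = "clinical"  # microbial | metabolite | clinical
    qtl_marker: str | None = None
    qtl_var: float = 0.0
    h2: float = 0.0
    founder_effects: np.ndarray | None = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    prevalence: float = 1.0
    nb_dispersion: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("h2 must lie in [0, 1)")
        if not (0.0 <= self.qtl_var < 1.0):
            raise ValueError("qtl_var must lie in [0, 1)")
        if self.trait_class not in ("microbial", "metabolite", "clinical"):
            raise ValueError(f"unknown trait class {self.trait_class!r}")
        if not (0.0 < self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in (0, 1]")


@dataclass
class PairSpec:
    """A microbe-metabolite trait pair with a known causal architecture."""

    name_a: str  # microbial member
    name_b: str  # metabolite member
    architecture: str
    qtl_marker: str | None = None
    qtl_marker_b: str | None = None  # second locus for "linked"/"independent"
    qtl_var: float = 0.2
    h2: float = 0.0
    mediation_strength: float = 1.0  # path coefficient for causal/reactive
    prevalence: float = 1.0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture tag {self.architecture!r}")


@dataclass
class SimTruth:
    """Ground truth of a simulated trait set: QTL positions, effect vectors,
    variance fractions and pair architectures, for recovery testing."""

    traits: dict[str, dict] = field(default_factory=dict)
    pairs: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump({"traits": self.traits, "pairs": self.pairs}, fh, indent=2, default=default, sort_keys=True)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def _draw_effects(rng: np.random.Generator) -> np.ndarray:
    e = rng.normal(size=8)
    return e - e.mean()


def _polygenic_draw(K_chol: np.ndarray | None, n: int, rng: np.random.Generator) -> np.ndarray:
    if K_chol is None:
        return rng.normal(size=n)
    return K_chol @ rng.normal(size=n)


def _kinship_factor(dosage: FounderDosage) -> np.ndarray:
    """Factor L with K = L L' for the genome-wide kinship (used to draw the
    polygenic term); eigendecomposition with negative eigenvalues clipped."""
    from pleioscan.scan import compute_kinship_overall

    K = compute_kinship_overall(dosage)
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def _latent_trait(
    dosage: FounderDosage,
    gmap: GeneticMap,
    spec: TraitSpec,
    covariates: pd.DataFrame | None,
    K_chol: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Latent Gaussian trait with the requested variance decomposition.

    QTL and polygenic components are standardized empirically, so sampled
    variance fractions closely match the requested values even at moderate n.
    """
    n = dosage.n_individuals
    truth: dict = {
        "class": spec.trait_class,
        "qtl_marker": spec.qtl_marker,
        "qtl_var": spec.qtl_var,
        "h2": spec.h2,
    }
    latent = np.zeros(n)
    if spec.qtl_marker is not None and spec.qtl_var > 0:
        m = gmap.marker_index(spec.qtl_marker)
        effects = spec.founder_effects
        if effects is None:
            effects = _draw_effects(rng)
        effects = np.asarray(effects, dtype=float)
        effects = effects - effects.mean()
        g = dosage.dosage[:, m, :] @ effects
        latent += np.sqrt(spec.qtl_var) * _standardize(g)
        truth["founder_effects"] = effects
        truth["qtl_chromosome"] = str(gmap.markers["chromosome"].iloc[m])
        truth["qtl_pos_cM"] = float(gmap.markers["pos_cM"].iloc[m])
    rest = 1.0 - spec.qtl_var
    if spec.h2 > 0:
        latent += np.sqrt(rest * spec.h2) * _standardize(_polygenic_draw(K_chol, n, rng))
    latent += np.sqrt(rest * (1.0 - spec.h2)) * rng.normal(size=n)
    if covariates is not None and spec.covariate_effects:
        for col, beta in spec.covariate_effects.items():
            latent += beta * _standardize(covariates[col].to_numpy().astype(float))
        truth["covariate_effects"] = dict(spec.covariate_effects)
    return latent, truth


def _counts_from_latent(
    latent: np.ndarray,
    prevalence: float,
    nb_dispersion: float,
    rng: np.random.Generator,
    lib: np.ndarray | None = None,
    baseline_log_mean: float = np.log(50.0),
    slope: float = 0.7,
) -> np.ndarray:
    """Over-dispersed counts via a negative binomial with log link.

    ``lib`` carries the per-sample library-size factors, shared by every
    feature of a count table (CSS exists to remove exactly this).  Requested
    prevalence is enforced by zeroing samples whose latent value falls below
    the (1 - prevalence) quantile, mimicking detection-limit sparsity that is
    correlated with true abundance.
    """
    n = len(latent)
    if lib is None:
        lib = np.exp(rng.normal(0.0, 0.3, size=n))
    mu = np.exp(baseline_log_mean + slope * latent) * lib
    theta = nb_dispersion
    # NB as Gamma-Poisson mixture
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam).astype(np.int64)
    if prevalence < 1.0:
        cutoff = np.quantile(latent, 1.0 - prevalence)
        counts[latent < cutoff] = 0
    return counts


def _areas_from_latent(
    latent: np.ndarray,
    rng: np.random.Generator,
    log_mean: float = np.log(1e5),
    scale: float = 0.5,
) -> np.ndarray:
    """Log-normal LC-MS peak areas from a latent trait (injection factors are
    applied jointly with the internal standard by the caller)."""
    return np.exp(log_mean + scale * latent)


def simulate_traits(
    dosage: FounderDosage,
    gmap: GeneticMap,
    covariates: pd.DataFrame | None,
    trait_specs: list[TraitSpec],
    pair_specs: list[PairSpec] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate trait tables with known truth.

    Returns ``(counts, metabolites, clinical, truth)``:

    * ``counts`` — individuals x microbial features, non-negative integers;
    * ``metabolites`` — individuals x metabolite peak areas, plus an
      ``IS_d4CDCA`` internal-standard column sharing each sample's injection
      factor, so internal-standard normalization can undo it;
    * ``clinical`` — individuals x clinical traits on the latent scale.

    Microbial/metabolite members of ``pair_specs`` are appended to the
    respective tables; their generating architecture is recorded in ``truth``.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(3)
    rng = np.random.default_rng(child[0])
    pair_rng = np.random.default_rng(child[1])
    obs_rng = np.random.default_rng(child[2])

    n = dosage.n_individuals
    idx = pd.Index(dosage.individuals, name="individual")
    needs_poly = any(s.h2 > 0 for s in trait_specs) or any(
        p.h2 > 0 for p in (pair_specs or [])
    )
    K_chol = _kinship_factor(dosage) if needs_poly else None

    truth = SimTruth()
    count_cols: dict[str, np.ndarray] = {}
    metab_cols: dict[str, np.ndarray] = {}
    clin_cols: dict[str, np.ndarray] = {}
    # one sequencing library-size factor per sample, shared across features
    lib = np.exp(obs_rng.normal(0.0, 0.3, size=n))

    def place(name: str, trait_class: str, latent: np.ndarray, prevalence: float, disp: float) -> None:
        if trait_class == "microbial":
            count_cols[name] = _counts_from_latent(latent, prevalence, disp, obs_rng, lib)
        elif trait_class == "metabolite":
            metab_cols[name] = _areas_from_latent(latent, obs_rng)
        else:
            clin_cols[name] = latent

    for spec in trait_specs:
        latent, t = _latent_trait(dosage, gmap, spec, covariates, K_chol, rng)
        truth.traits[spec.name] = t
        place(spec.name, spec.trait_class, latent, spec.prevalence, spec.nb_dispersion)

    for pspec in pair_specs or []:
        la, lb, pair_truth = _architecture_pair(dosage, gmap, pspec, covariates, K_chol, pair_rng)
        truth.traits[pspec.name_a] = pair_truth["truth_a"]
        truth.traits[pspec.name_b] = pair_truth["truth_b"]
        truth.pairs[f"{pspec.name_a}|{pspec.name_b}"] = {
            "architecture": pspec.architecture,
            **{k: v for k, v in pair_truth.items() if not k.startswith("truth_")},
        }
        place(pspec.name_a, "microbial", la, pspec.prevalence, 5.0)
        place(pspec.name_b, "metabolite", lb, 1.0, 5.0)

    counts = pd.DataFrame(count_cols, index=idx)
    clinical = pd.DataFrame(clin_cols, index=idx)
    # shared per-sample injection factor links metabolites to the IS channel
    inj = np.exp(obs_rng.normal(0.0, 0.3, size=n))
    is_base = np.exp(obs_rng.normal(np.log(5e4), 0.1, size=n))
    metabolites = pd.DataFrame({k: v * inj for k, v in metab_cols.items()}, index=idx)
    metabolites["IS_d4CDCA"] = is_base * inj
    return counts, metabolites, clinical, truth


def _architecture_pair(
    dosage: FounderDosage,
    gmap: GeneticMap,
    pspec: PairSpec,
    covariates: pd.DataFrame | None,
    K_chol: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Latent trait pair under one of the five causal architectures.

    pleiotropic — one locus, each trait its own noise, shared effect vector;
    linked — two distinct loci on the same chromosome; causal — locus ->
    microbe -> metabolite with no direct edge (so target _||_ locus given the
    mediator); reactive — the mirror image; independent — unrelated loci (or
    none) and independent noise.
    """
    arch = pspec.architecture
    base = TraitSpec(
        name=pspec.name_a,
        qtl_marker=pspec.qtl_marker,
        qtl_var=pspec.qtl_var,
        h2=pspec.h2,
    )
    info: dict = {}
    if arch == "pleiotropic":
        effects = _draw_effects(rng)
        sa = TraitSpec(pspec.name_a, qtl_marker=pspec.qtl_marker, qtl_var=pspec.qtl_var, h2=pspec.h2, founder_effects=effects)
        sb = TraitSpec(pspec.name_b, qtl_marker=pspec.qtl_marker, qtl_var=pspec.qtl_var, h2=pspec.h2, founder_effects=effects)
        la, ta = _latent_trait(dosage, gmap, sa, covariates, K_chol, rng)
        lb, tb = _latent_trait(dosage, gmap, sb, covariates, K_chol, rng)
    elif arch == "linked":
        if pspec.qtl_marker_b is None:
            raise ValueError("linked architecture needs qtl_marker_b")
        sa = TraitSpec(pspec.name_a, qtl_marker=pspec.qtl_marker, qtl_var=pspec.qtl_var, h2=pspec.h2)
        sb = TraitSpec(pspec.name_b, qtl_marker=pspec.qtl_marker_b, qtl_var=pspec.qtl_var, h2=pspec.h2)
        la, ta = _latent_trait(dosage, gmap, sa, covariates, K_chol, rng)
        lb, tb = _latent_trait(dosage, gmap, sb, covariates, K_chol, rng)
    elif arch in ("causal", "reactive"):
        # source trait carries the QTL; downstream trait receives it only
        # through the mediation path
        s_src = TraitSpec("src", qtl_marker=pspec.qtl_marker, qtl_var=pspec.qtl_var, h2=pspec.h2)
        l_src, t_src = _latent_trait(dosage, gmap, s_src, covariates, K_chol, rng)
        b = pspec.mediation_strength
        l_dst = b * _standardize(l_src) + rng.normal(size=dosage.n_individuals)
        t_dst = {
            "class": None,
            "qtl_marker": None,
            "mediated_from": pspec.name_a if arch == "causal" else pspec.name_b,
            "path_coefficient": b,
        }
        if arch == "causal":
            la, ta, lb, tb = l_src, t_src, l_dst, t_dst
        else:
            la, ta, lb, tb = l_dst, t_dst, l_src, t_src
    elif arch == "independent":
        sa = TraitSpec(pspec.name_a, qtl_marker=pspec.qtl_marker, qtl_var=pspec.qtl_var if pspec.qtl_marker else 0.0, h2=pspec.h2)
        sb = TraitSpec(pspec.name_b, qtl_marker=pspec.qtl_marker_b, qtl_var=pspec.qtl_var if pspec.qtl_marker_b else 0.0, h2=pspec.h2)
        la, ta = _latent_trait(dosage, gmap, sa, covariates, K_chol, rng)
        lb, tb = _latent_trait(dosage, gmap, sb, covariates, K_chol, rng)
    else:  # pragma: no cover - guarded in PairSpec
        raise ValueError(arch)
    ta["class"] = "microbial"
    tb["class"] = "metabolite"
    info["truth_a"] = ta
    info["truth_b"] = tb
    return la, lb, info


def simulate_taxonomy(feature_names: list[str], seed: int | None = None) -> pd.Series:
    """Greengenes-style lineage strings for simulated features, drawn from a
    small fixed pool of phyla/families/genera."""
    rng = np.random.default_rng(seed)
    phyla = ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Verrucomicrobia"]
    families = {
        "Firmicutes": [("Clostridia", "Clostridiales", "Lachnospiraceae"), ("Bacilli", "Turicibacterales", "Turicibacteraceae")],
        "Bacteroidetes": [("Bacteroidia", "Bacteroidales", "S24-7")],
        "Proteobacteria": [("Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae")],
        "Verrucomicrobia": [("Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae")],
    }
    lineages = []
    for name in feature_names:
        p = phyla[rng.integers(len(phyla))]
        cls, order, fam = families[p][rng.integers(len(families[p]))]
        genus = f"Genus{rng.integers(1, 6)}"
        lineages.append(
            f"k__Bacteria;p__{p};c__{cls};o__{order};f__{fam};g__{genus};s__"
        )
    return pd.Series(lineages, index=feature_names, name="taxonomy")
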