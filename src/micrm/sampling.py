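"""Random generation of structured regional species pools.

A regional pool consists of a binary-valued consumer preference matrix
``c`` (who eats what, and how fast), a column-stochastic metabolic matrix
``D`` (which byproducts are secreted when a given resource is consumed),
and per-species maintenance costs.  Taxonomic structure enters through
specialist families that preferentially consume one resource class;
metabolic structure enters through a three-tiered secretion model in
which byproducts flow preferentially to a designated "waste" class and
to the class of the input resource.

All sampling is a pure function of (parameters, seed): replaying with
the same seed reproduces the pool bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GlobalParameters",
    "ResourceSchema",
    "RegionalPool",
    "Environment",
    "emp_parameters",
    "hmp_parameters",
    "sample_consumer_matrix",
    "sample_metabolic_matrix",
    "sample_maintenance",
    "make_supply",
    "sample_pool",
    "save_pool",
    "load_pool",
]

GENERALIST = -1  # family code for species with no class preference


def _substream(master_seed: int, stream: int) -> np.random.Generator:
    """Derive an independent generator from a master seed by fixed offset."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(stream))))


@dataclass(frozen=True)
class GlobalParameters:
    """Global parameters defining a randomly sampled ecosystem.

    Defaults are the human-microbiome configuration: a pool of 5000
    species in 6 specialist families of 800 plus 200 generalists,
    consuming 300 resources grouped into 6 classes of 50.
    """

    M: int = 300            # number of resource types
    T: int = 6              # number of resource classes
    S_tot: int = 5000       # regional pool size
    F: int = 6              # number of specialist families
    S: int = 2500           # species colonizing each local community
    mu_c: float = 10.0      # target mean row sum of the consumer matrix
    c0: float = 0.0         # background (low) consumption level
    c1: float = 1.0         # high consumption level
    q: float = 0.9          # fraction of capacity on the preferred class
    s: float = 0.3          # metabolic matrix sparsity, in (0, 1]
    f_w: float = 0.45       # mean secreted fraction to the waste class
    f_s: float = 0.45       # mean secreted fraction to the same class
    m_mean: float = 1.0     # maintenance cost mean (energy/time)
    m_sd: float = 0.01      # maintenance cost standard deviation
    l: float = 0.8          # leakage fraction per resource
    g: float = 1.0          # energy-to-growth conversion
    w: float = 1.0          # energy content per unit resource
    tau_R: float = 1.0      # resource dilution timescale
    n_generalists: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not (0.0 < self.s <= 1.0):
            raise ValueError(f"s must lie in (0, 1], got {self.s}")
        if self.f_w < 0 or self.f_s < 0 or self.f_w + self.f_s > 1.0 + 1e-12:
            raise ValueError(f"need f_w, f_s >= 0 and f_w + f_s <= 1, got {self.f_w}, {self.f_s}")
        if self.F > self.T:
            raise ValueError(f"more specialist families ({self.F}) than resource classes ({self.T})")
        if self.S > self.S_tot:
            raise ValueError(f"S={self.S} exceeds pool size S_tot={self.S_tot}")
        if self.M % self.T != 0:
            raise ValueError(f"M={self.M} not divisible by T={self.T}; classes must be equal-sized")
        if self.n_generalists > self.S_tot:
            raise ValueError("more generalists than species in the pool")
        if self.m_sd < 0:
            raise ValueError("m_sd must be non-negative")
        if self.S < 1 or self.S_tot < 1 or self.M < 1 or self.T < 1 or self.F < 1:
            raise ValueError("counts must be positive")

    @property
    def family_size(self) -> int:
        """Species per specialist family; remainders go to the generalists."""
        return (self.S_tot - self.n_generalists) // self.F

    @property
    def n_generalists_effective(self) -> int:
        return self.S_tot - self.F * self.family_size

    @property
    def M_A(self) -> int:
        """Resources per class (classes are equal-sized)."""
        return self.M // self.T

    def replace(self, **kwargs) -> "GlobalParameters":
        return dataclasses.replace(self, **kwargs)


def emp_parameters(scale: float = 1.0, **overrides) -> GlobalParameters:
    """Unstructured-pool configuration used for the global-survey scenarios.

    One resource class, one family, 180 species on 90 resources, binary
    preferences with c0=0, c1=1, mu_c=10 and a sparse (s=0.05) metabolic
    matrix.  ``scale`` shrinks S_tot, M and S proportionally.  With a
    single class every resource belongs to the waste class, so f_w=1
    keeps the total Dirichlet concentration at 1/s and the sparsity
    parameter retains its meaning.
    """
    defaults = dict(
        M=max(1, round(90 * scale)),
        T=1,
        S_tot=max(2, round(180 * scale)),
        F=1,
        S=max(1, round(150 * scale)),
        mu_c=10.0,
        c0=0.0,
        c1=1.0,
        q=0.0,
        s=0.05,
        f_w=1.0,
        f_s=0.0,
        n_generalists=0,
    )
    defaults["S"] = min(defaults["S"], defaults["S_tot"])
    defaults.update(overrides)
    return GlobalParameters(**defaults)


def hmp_parameters(scale: float = 1.0, dispersal: str = "strong", **overrides) -> GlobalParameters:
    """Structured-pool configuration used for the host-associated scenarios.

    5000 species (6 families x 800 + 200 generalists) on 300 resources in
    6 classes, q=0.9, s=0.3, f_s=f_w=0.45.  ``dispersal`` picks the
    colonization size: "strong" limitation (S=2500) or "weak" (S=4900).
    ``scale`` shrinks pool, resources and colonization proportionally
    while preserving T, F, q, s and the secretion fractions.
    """
    if dispersal not in ("strong", "weak"):
        raise ValueError(f"dispersal must be 'strong' or 'weak', got {dispersal!r}")
    T = 6
    M = max(T, T * round(300 * scale / T))
    fam = max(1, round(800 * scale))
    n_gen = max(0, round(200 * scale))
    S_tot = 6 * fam + n_gen
    S_frac = 2500 / 5000 if dispersal == "strong" else 4900 / 5000
    defaults = dict(
        M=M,
        T=T,
        S_tot=S_tot,
        F=6,
        S=max(1, min(S_tot, round(S_frac * S_tot))),
        mu_c=10.0,
        c0=0.0,
        c1=1.0,
        q=0.9,
        s=0.3,
        f_w=0.45,
        f_s=0.45,
        n_generalists=n_gen,
    )
    defaults.update(overrides)
    return GlobalParameters(**defaults)


@dataclass(frozen=True)
class ResourceSchema:
    """Partition of the resources into equal-sized classes.

    Classes are labeled A, B, C, ... and the waste class (the preferred
    byproduct destination) is by convention the last one.
    """

    class_of: np.ndarray            # int class index per resource
    class_labels: tuple[str, ...]
    waste_class: int                # index into class_labels

    def __post_init__(self) -> None:
        if not (0 <= self.waste_class < len(self.class_labels)):
            raise ValueError("waste_class out of range")

    @classmethod
    def from_params(cls, params: GlobalParameters, waste_class: int | None = None) -> "ResourceSchema":
        M_A = params.M_A
        class_of = np.repeat(np.arange(params.T), M_A)
        labels = tuple(string.ascii_uppercase[: params.T])
        wc = params.T - 1 if waste_class is None else waste_class
        return cls(class_of=class_of, class_labels=labels, waste_class=wc)

    @property
    def M(self) -> int:
        return self.class_of.size

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.class_of, minlength=self.n_classes)

    @property
    def M_w(self) -> int:
        return int(self.class_sizes()[self.waste_class])

    def class_index(self, label: str) -> int:
        try:
            return self.class_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown resource class {label!r}") from None

    def resources_in_class(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.class_of == self.class_index(label))


@dataclass(frozen=True)
class Environment:
    """External conditions a community experiences.

    ``kappa`` is the vector of external resource supply rates,
    ``m_env`` a scalar harshness offset added to every species'
    maintenance cost, and ``tau_R`` the resource dilution timescale.
    """

    kappa: np.ndarray
    m_env: float = 0.0
    tau_R: float = 1.0

    def __post_init__(self) -> None:
        kappa = np.asarray(self.kappa, dtype=float)
        if np.any(kappa < 0):
            raise ValueError("supply rates must be non-negative")
        if not np.all(np.isfinite(kappa)):
            raise ValueError("supply rates must be finite")
        object.__setattr__(self, "kappa", kappa)
        if self.tau_R <= 0:
            raise ValueError("tau_R must be positive")


@dataclass(frozen=True)
class RegionalPool:
    """A sampled regional species pool.

    ``c`` is the S_tot x M consumer preference matrix, ``D`` the M x M
    column-stochastic metabolic matrix, ``m_base`` the vector of
    maintenance costs, and ``family_of`` maps species to specialist
    family index (GENERALIST = -1 for generalists).
    """

    c: np.ndarray
    D: np.ndarray
    m_base: np.ndarray
    family_of: np.ndarray
    schema: ResourceSchema
    params: GlobalParameters
    seed: int

    def __post_init__(self) -> None:
        if self.c.shape != (self.params.S_tot, self.params.M):
            raise ValueError("consumer matrix has wrong shape")
        if self.D.shape != (self.params.M, self.params.M):
            raise ValueError("metabolic matrix has wrong shape")
        colsums = self.D.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-12):
            raise ValueError("metabolic matrix columns must sum to 1")
        if np.any(self.c < 0) or np.any(self.D < 0) or np.any(self.m_base < 0):
            raise ValueError("pool matrices must be non-negative")

    @property
    def S_tot(self) -> int:
        return self.params.S_tot

    @property
    def M(self) -> int:
        return self.params.M

    def family_labels(self) -> np.ndarray:
        """String label per species: the preferred class letter, or 'gen'."""
        labels = np.empty(self.S_tot, dtype=object)
        for i, fam in enumerate(self.family_of):
            labels[i] = "gen" if fam == GENERALIST else self.schema.class_labels[fam]
        return labels


def _family_assignment(params: GlobalParameters) -> np.ndarray:
    fam = np.full(params.S_tot, GENERALIST, dtype=int)
    size = params.family_size
    for A in range(params.F):
        fam[A * size : (A + 1) * size] = A
    return fam


def consumption_probabilities(params: GlobalParameters, schema: ResourceSchema) -> np.ndarray:
    """Bernoulli probability of a high consumption level, per species x resource.

    Specialists concentrate a fraction q of their consumption capacity
    on their preferred class; generalists use the uniform probability
    mu_c / (M c1) everywhere.
    """
    base = params.mu_c / (params.M * params.c1)
    M_A = params.M_A
    family_of = _family_assignment(params)
    p = np.full((params.S_tot, params.M), base)
    p_pref = base * (1.0 + (params.M - M_A) / M_A * params.q)
    p_off = base * (1.0 - params.q)
    for A in range(params.F):
        rows = family_of == A
        in_class = schema.class_of == A
        p[np.ix_(rows, ~in_class)] = p_off
        p[np.ix_(rows, in_class)] = p_pref
    if np.any(p > 1.0 + 1e-12):
        raise ValueError(
            "consumption probability exceeds 1; the combination "
            f"(mu_c={params.mu_c}, c1={params.c1}, M={params.M}, q={params.q}) is invalid"
        )
    if np.any(p < 0):
        raise ValueError("negative consumption probability")
    return p


def sample_consumer_matrix(
    params: GlobalParameters, schema: ResourceSchema, rng_seed,
    distribution: str = "binary",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the binary consumer preference matrix.

    Each entry equals c0/M plus c1 times a Bernoulli variable whose
    probability depends on whether the species' family prefers the
    resource's class.  Returns (c, family_of).

    Gaussian and Gamma preference variants exist in the literature but
    all results here use the binary model; requesting them raises.
    """
    if distribution != "binary":
        raise NotImplementedError(
            f"only the binary preference model is implemented, not {distribution!r}"
        )
    rng = np.random.default_rng(rng_seed)
    p = consumption_probabilities(params, schema)
    X = rng.random(p.shape) < p
    c = params.c0 / params.M + params.c1 * X
    return c, _family_assignment(params)


def metabolic_concentrations(params: GlobalParameters, schema: ResourceSchema) -> np.ndarray:
    """Dirichlet concentration parameters d[alpha, beta] of the secretion model.

    Column beta (the consumed resource) allocates, on average, a
    fraction f_w of the secreted flux to the waste class, f_s to the
    class of beta, and the remainder to everything else; when beta
    itself is a waste resource, the same-class and waste tiers merge.
    The sparsity s scales all concentrations by 1/s, so s -> 1 gives
    near-single-output columns and s -> 0 a dense network.
    """
    M = params.M
    class_of = schema.class_of
    w = schema.waste_class
    sizes = schema.class_sizes()
    M_w = int(sizes[w])
    d = np.zeros((M, M))
    is_waste_row = class_of == w
    for beta in range(M):
        A_b = class_of[beta]
        if A_b != w:
            M_A = int(sizes[A_b])
            same = class_of == A_b
            other = ~(same | is_waste_row)
            n_other = int(other.sum())
            d[is_waste_row, beta] = params.f_w / (params.s * M_w)
            d[same, beta] = params.f_s / (params.s * M_A)
            if n_other > 0:
                conc = (1.0 - params.f_s - params.f_w) / (params.s * n_other)
                if conc <= 0:
                    raise ValueError(
                        "non-positive Dirichlet concentration for the 'other' tier; "
                        "f_w + f_s = 1 requires that no third tier exist"
                    )
                d[other, beta] = conc
        else:
            d[is_waste_row, beta] = (params.f_w + params.f_s) / (params.s * M_w)
            other = ~is_waste_row
            n_other = int(other.sum())
            if n_other > 0:
                conc = (1.0 - params.f_w - params.f_s) / (params.s * n_other)
                if conc <= 0:
                    raise ValueError(
                        "non-positive Dirichlet concentration for the non-waste tier "
                        "of a waste-input column"
                    )
                d[other, beta] = conc
    if np.any(d.sum(axis=0) <= 0):
        raise ValueError("every column needs at least one positive concentration")
    return d


def sample_metabolic_matrix(
    params: GlobalParameters, schema: ResourceSchema, rng_seed
) -> np.ndarray:
    """Draw the column-stochastic metabolic matrix D.

    Each column is a Dirichlet sample with the tiered concentration
    parameters above, so each column sums to exactly 1.
    """
    rng = np.random.default_rng(rng_seed)
    d = metabolic_concentrations(params, schema)
    D = np.empty_like(d)
    for beta in range(params.M):
        D[:, beta] = rng.dirichlet(d[:, beta])
    # exact renormalization guards against accumulated rounding
    D /= D.sum(axis=0, keepdims=True)
    return D


def sample_maintenance(params: GlobalParameters, rng_seed) -> np.ndarray:
    """Draw per-species maintenance costs from N(m_mean, m_sd)."""
    rng = np.random.default_rng(rng_seed)
    m = rng.normal(params.m_mean, params.m_sd, size=params.S_tot)
    if np.any(m <= 0):
        raise ValueError(
            "sampled a non-positive maintenance cost; increase m_mean or decrease m_sd"
        )
    return m


def make_supply(
    kind: str,
    schema: ResourceSchema,
    total_flux: float,
    spec: dict | None = None,
    rng_seed=None,
) -> np.ndarray:
    """Build an external supply vector kappa summing to ``total_flux``.

    kind="single"        {"resource": index}: all flux on one resource.
    kind="pair"          {"resources": (i, j), "a": fraction}: flux split
                         as ((1-a), a) between two resources.
    kind="class_uniform" {"classes": (label, label)}: uniformly-random
                         weights over all resources of the named classes,
                         normalized to total_flux.
    kind="random_subset" {"n": count} or {"resources": indices}:
                         uniformly-random weights over a random (or
                         given) subset, normalized.
    """
    spec = dict(spec or {})
    if total_flux <= 0:
        raise ValueError("total_flux must be positive")
    M = schema.M
    kappa = np.zeros(M)
    if kind == "single":
        idx = int(spec.get("resource", 0))
        if not (0 <= idx < M):
            raise ValueError(f"resource index {idx} out of range")
        kappa[idx] = total_flux
    elif kind == "pair":
        i, j = spec["resources"]
        a = float(spec["a"])
        if not (0.0 <= a <= 1.0):
            raise ValueError(f"mixing fraction a={a} outside [0, 1]")
        if not (0 <= i < M and 0 <= j < M):
            raise ValueError("resource index out of range")
        kappa[int(i)] = (1.0 - a) * total_flux
        kappa[int(j)] = a * total_flux
    elif kind == "class_uniform":
        labels = spec["classes"]
        members = np.concatenate([schema.resources_in_class(lab) for lab in labels])
        if members.size == 0:
            raise ValueError("empty resource selection")
        rng = np.random.default_rng(rng_seed)
        weights = rng.uniform(0.0, 1.0, size=members.size)
        kappa[members] = total_flux * weights / weights.sum()
    elif kind == "random_subset":
        rng = np.random.default_rng(rng_seed)
        if "resources" in spec:
            members = np.asarray(spec["resources"], dtype=int)
        else:
            n = int(spec["n"])
            if not (1 <= n <= M):
                raise ValueError(f"subset size {n} out of range")
            members = rng.choice(M, size=n, replace=False)
        if members.size == 0:
            raise ValueError("empty resource selection")
        weights = rng.uniform(0.0, 1.0, size=members.size)
        kappa[members] = total_flux * weights / weights.sum()
    else:
        raise ValueError(f"unknown supply kind {kind!r}")
    return kappa


def sample_pool(
    params: GlobalParameters, seed: int, waste_class: int | None = None
) -> RegionalPool:
    """Sample a full regional pool from a master seed.

    The consumer matrix, metabolic matrix and maintenance costs each use
    an independent stream derived from the master seed by a fixed
    offset, so individual components can be replayed.
    """
    schema = ResourceSchema.from_params(params, waste_class=waste_class)
    c, family_of = sample_consumer_matrix(params, schema, _substream(seed, 0))
    D = sample_metabolic_matrix(params, schema, _substream(seed, 1))
    m_base = sample_maintenance(params, _substream(seed, 2))
    return RegionalPool(
        c=c, D=D, m_base=m_base, family_of=family_of, schema=schema, params=params, seed=seed
    )


def save_pool(pool: RegionalPool, directory) -> None:
    """Serialize a pool to a directory of TSV matrices plus JSON metadata."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    species = [f"sp{i:05d}" for i in range(pool.S_tot)]
    resources = [f"res{a:04d}" for a in range(pool.M)]
    pd.DataFrame(pool.c, index=species, columns=resources).to_csv(
        directory / "consumer_matrix.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(pool.D, index=resources, columns=resources).to_csv(
        directory / "metabolic_matrix.tsv", sep="\t", float_format="%.17g"
    )
    meta = {
        "params": dataclasses.asdict(pool.params),
        "seed": pool.seed,
        "waste_class": pool.schema.waste_class,
        "class_labels": list(pool.schema.class_labels),
        "m_base": pool.m_base.tolist(),
        "family_of": pool.family_of.tolist(),
    }
    (directory / "pool.json").write_text(json.dumps(meta, indent=1))


def load_pool(directory) -> RegionalPool:
    """Load a pool serialized by :func:`save_pool`."""
    directory = pathlib.Path(directory)
    meta = json.loads((directory / "pool.json").read_text())
    params = GlobalParameters(**meta["params"])
    schema = ResourceSchema.from_params(params, waste_class=meta["waste_class"])
    c = pd.read_csv(directory / "consumer_matrix.tsv", sep="\t", index_col=0, float_precision="round_trip").to_numpy(float)
    D = pd.read_csv(directory / "metabolic_matrix.tsv", sep="\t", index_col=0, float_precision="round_trip").to_numpy(float)
    # round-trip through text can perturb column sums at the last digit
    D /= D.sum(axis=0, keepdims=True)
    return RegionalPool(
        c=c,
        D=D,
        m_base=np.asarray(meta["m_base"], dtype=float),
        family_of=np.asarray(meta["family_of"], dtype=int),
        schema=schema,
        params=params,
        seed=meta["seed"],
    )
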