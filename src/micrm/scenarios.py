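"""Simulation campaigns reproducing large-survey biodiversity settings.

Three families of scenarios are provided:

* ``run_emp`` — an unstructured 180-species / 90-resource pool whose
  samples differ in environmental harshness (a random additive offset
  to all maintenance costs) and/or colonization size, mirroring
  global-survey richness and nestedness analyses.
* ``run_hmp`` — a structured 5000-species / 300-resource pool with six
  specialist families and six resource classes; three "body sites" are
  supplied with resources from different class pairs (or random
  subsets), mirroring host-associated survey patterns.
* ``run_mixture`` — two-resource mixture experiments where every
  community is initialized with the full regional pool, used to test
  additivity of community composition across nutrient gradients.

A ``scale`` factor shrinks pool size, resource count and sample count
proportionally while preserving the structural parameters (T, F, q, s,
f_w, f_s, l), so the qualitative patterns survive desk-scale runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import colonize, CommunityState, integrate_to_steady_state
from .sampling import (
    Environment,
    GlobalParameters,
    RegionalPool,
    emp_parameters,
    hmp_parameters,
    make_supply,
    sample_pool,
)

__all__ = ["ScenarioConfig", "AbundanceTable", "run_emp", "run_hmp", "run_mixture"]

EMP_KINDS = ("simple", "complex", "dispersal_limited", "mixed")
HMP_TYPES = ("distinct_simple", "distinct_complex", "no_taxonomy", "overlapping_complex")
SITE_CLASS_PAIRS = (("A", "B"), ("C", "D"), ("E", "F"))


@dataclass
class ScenarioConfig:
    """Declarative description of a simulation campaign."""

    name: str = "hmp"
    kind: str = "distinct_simple"       # EMP kind or HMP environment type
    dispersal: str = "strong"           # HMP colonization level
    scale: float = 1.0
    n_samples: int | None = None        # per site for HMP; total for EMP
    master_seed: int = 0
    total_flux: float = 1000.0
    residual_tol: float = 1e-6
    t_max: float = 1e4
    rtol: float = 1e-7
    share_pool: bool = True             # one pool per scenario (the default)
    params_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples is not None and self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.name not in ("emp", "hmp", "mixture"):
            raise ValueError(f"unknown scenario family {self.name!r}")


@dataclass
class AbundanceTable:
    """Samples x species equilibrium abundances with per-sample metadata.

    Non-converged samples are retained but flagged; analyses are
    expected to filter on ``sample_meta['converged']``.
    """

    values: pd.DataFrame                  # samples x S_tot
    sample_meta: pd.DataFrame             # site, m_env, n_colonists, seed, converged, ...
    species_meta: pd.DataFrame            # family label per species
    pool: RegionalPool | None = None
    supply: pd.DataFrame | None = None    # samples x M external supply vectors

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("sample metadata must align with abundance rows")
        if list(self.values.columns) != list(self.species_meta.index):
            raise ValueError("species metadata must align with abundance columns")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def converged(self) -> "AbundanceTable":
        """Restrict to converged samples (the standard discard rule)."""
        keep = self.sample_meta["converged"].to_numpy(bool)
        return AbundanceTable(
            values=self.values.loc[keep],
            sample_meta=self.sample_meta.loc[keep],
            species_meta=self.species_meta,
            pool=self.pool,
            supply=None if self.supply is None else self.supply.loc[keep],
        )

    def n_discarded(self) -> int:
        return int((~self.sample_meta["converged"].to_numpy(bool)).sum())


def _species_meta(pool: RegionalPool) -> pd.DataFrame:
    ids = [f"sp{i:05d}" for i in range(pool.S_tot)]
    return pd.DataFrame({"family": pool.family_labels()}, index=pd.Index(ids, name="species"))


def _run_batch(pool, envs, initials, cfg, extra_meta, pools=None) -> AbundanceTable:
    rows, meta = [], []
    for j, (env, init) in enumerate(zip(envs, initials)):
        res = integrate_to_steady_state(
            pool if pools is None else pools[j],
            env,
            init,
            residual_tol=cfg.residual_tol,
            t_max=cfg.t_max,
            rtol=cfg.rtol,
        )
        rows.append(res.N_bar)
        rec = {
            "m_env": env.m_env,
            "n_colonists": int(res.colonists.size),
            "richness": res.richness,
            "converged": res.converged,
            "max_residual": res.max_residual,
        }
        rec.update(extra_meta[j])
        meta.append(rec)
    ids = [f"sample{j:04d}" for j in range(len(rows))]
    values = pd.DataFrame(
        np.asarray(rows), index=pd.Index(ids, name="sample"),
        columns=_species_meta(pool).index,
    )
    sample_meta = pd.DataFrame(meta, index=values.index)
    supply = pd.DataFrame(
        np.asarray([e.kappa for e in envs]), index=values.index,
        columns=[f"res{a:04d}" for a in range(pool.M)],
    )
    return AbundanceTable(
        values=values, sample_meta=sample_meta, species_meta=_species_meta(pool),
        pool=pool, supply=supply,
    )


def run_emp(
    kind: str = "simple",
    scale: float = 1.0,
    n_samples: int | None = None,
    master_seed: int = 0,
    config: ScenarioConfig | None = None,
) -> AbundanceTable:
    """Global-survey scenario: harshness and/or dispersal variation.

    kind="simple":            150 colonists, single supplied resource
                              (kappa_1 = 200), harshness m_env ~ U(-0.5, 9.5).
    kind="complex":           as simple, but the 200 units of supply are
                              spread evenly over all resources.
    kind="dispersal_limited": colonization size uniform on {1..S_tot},
                              single resource, fixed m_env = 0.
    kind="mixed":             both harshness and colonization size vary.

    Matched comparisons across kinds reuse the same per-sample random
    draws: the harshness value, colonist subset and solver seeds depend
    only on (master_seed, sample index), not on the kind.
    """
    if kind not in EMP_KINDS:
        raise ValueError(f"kind must be one of {EMP_KINDS}, got {kind!r}")
    cfg = config or ScenarioConfig(name="emp", kind=kind, scale=scale, master_seed=master_seed)
    params = emp_parameters(scale=scale, **cfg.params_overrides)
    n = n_samples if n_samples is not None else max(2, round(300 * scale))
    pool = sample_pool(params, master_seed)
    pools = None
    if not cfg.share_pool:
        pools = [
            sample_pool(params, int(np.random.SeedSequence((master_seed, 2, j)).generate_state(1)[0] % (2**31)))
            for j in range(n)
        ]

    envs, initials, extra = [], [], []
    for j in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((master_seed, 1, j)))
        # identical draw order across kinds keeps samples matched
        m_env_draw = rng.uniform(-0.5, 9.5)
        S_draw = int(rng.integers(1, params.S_tot + 1))
        colonist_seed = rng.integers(0, 2**31)

        if kind == "simple" or kind == "complex":
            m_env, S = m_env_draw, params.S
        elif kind == "dispersal_limited":
            m_env, S = 0.0, S_draw
        else:  # mixed
            m_env, S = m_env_draw, S_draw

        if kind == "complex":
            kappa = np.full(params.M, 200.0 / params.M)
        else:
            kappa = make_supply("single", pool.schema, 200.0, {"resource": 0})
        envs.append(Environment(kappa=kappa, m_env=m_env, tau_R=params.tau_R))
        initials.append(colonize(pool, S, colonist_seed))
        extra.append({"site": "emp", "kind": kind, "sample_seed": int(colonist_seed)})
    return _run_batch(pool, envs, initials, cfg, extra, pools=pools)


def run_hmp(
    environment_type: str = "distinct_simple",
    dispersal: str = "strong",
    scale: float = 1.0,
    n_per_site: int | None = None,
    master_seed: int = 0,
    config: ScenarioConfig | None = None,
) -> AbundanceTable:
    """Host-associated scenario: three body sites with distinct nutrient supply.

    environment_type selects how sites differ:
      distinct_simple      one resource from each of two classes per site
                           (A+B, C+D, E+F), fluxes split (1-a, a) with
                           a ~ U(0, 1) per sample;
      distinct_complex     all resources of the two site classes, with
                           uniformly-random weights per sample;
      no_taxonomy          as distinct_simple but q = 0 (no specialist
                           families), same supply draws;
      overlapping_complex  the resources are randomly partitioned into
                           three equal sets, one per site, supplied with
                           random weights.

    dispersal="strong" colonizes each sample with half the pool,
    "weak" with 98% of it.  Total supplied flux is 1000 per sample.
    """
    if environment_type not in HMP_TYPES:
        raise ValueError(f"environment_type must be one of {HMP_TYPES}")
    cfg = config or ScenarioConfig(
        name="hmp", kind=environment_type, dispersal=dispersal, scale=scale,
        master_seed=master_seed,
    )
    overrides = dict(cfg.params_overrides)
    if environment_type == "no_taxonomy":
        overrides["q"] = 0.0
    params = hmp_parameters(scale=scale, dispersal=dispersal, **overrides)
    n_site = n_per_site if n_per_site is not None else max(1, round(300 * scale))
    pool = sample_pool(params, master_seed)
    schema = pool.schema

    partition = None
    if environment_type == "overlapping_complex":
        rng = np.random.default_rng(np.random.SeedSequence((master_seed, 999)))
        perm = rng.permutation(params.M)
        partition = np.array_split(perm, 3)

    envs, initials, extra = [], [], []
    j_global = 0
    for site_idx, (clsA, clsB) in enumerate(SITE_CLASS_PAIRS):
        for j in range(n_site):
            rng = np.random.default_rng(np.random.SeedSequence((master_seed, 1, j_global)))
            a = rng.uniform(0.0, 1.0)
            supply_seed = rng.integers(0, 2**31)
            colonist_seed = rng.integers(0, 2**31)
            rec = {"site": f"site{site_idx + 1}", "sample_seed": int(colonist_seed)}

            if environment_type in ("distinct_simple", "no_taxonomy"):
                rA = schema.resources_in_class(clsA)[0]
                rB = schema.resources_in_class(clsB)[0]
                kappa = make_supply(
                    "pair", schema, cfg.total_flux, {"resources": (rA, rB), "a": a}
                )
                rec["a"] = a
            elif environment_type == "distinct_complex":
                kappa = make_supply(
                    "class_uniform", schema, cfg.total_flux,
                    {"classes": (clsA, clsB)}, rng_seed=supply_seed,
                )
            else:  # overlapping_complex
                kappa = make_supply(
                    "random_subset", schema, cfg.total_flux,
                    {"resources": partition[site_idx]}, rng_seed=supply_seed,
                )
            envs.append(Environment(kappa=kappa, m_env=0.0, tau_R=params.tau_R))
            initials.append(colonize(pool, params.S, colonist_seed))
            extra.append(rec)
            j_global += 1
    return _run_batch(pool, envs, initials, cfg, extra)


def run_mixture(
    structured: bool = True,
    classes: tuple[str, str] = ("A", "B"),
    a_values: tuple[float, ...] = (0.0, 1.0, 0.5),
    n_replicates: int = 1,
    scale: float = 1.0,
    master_seed: int = 0,
    config: ScenarioConfig | None = None,
) -> AbundanceTable:
    """Two-resource mixture experiment with full-pool initialization.

    For each replicate (a fresh pool per replicate) one community is run
    per mixing fraction ``a``: flux (1-a)*kappa on the first resource
    and a*kappa on the second, total flux constant.  With
    ``structured=False`` all resources are assigned to a single class
    (T = F = 1) before sampling, removing metabolic and taxonomic
    structure; the two supplied resources are then simply the first two.
    """
    cfg = config or ScenarioConfig(name="mixture", kind="mixture", scale=scale,
                                   master_seed=master_seed)
    for a in a_values:
        if not (0.0 <= a <= 1.0):
            raise ValueError(f"mixing fraction a={a} outside [0, 1]")

    tables = []
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence((master_seed, rep)).generate_state(1)[0] % (2**31))
        if structured:
            params = hmp_parameters(scale=scale, **cfg.params_overrides)
        else:
            base = hmp_parameters(scale=scale)
            params = GlobalParameters(
                **{
                    **dataclasses.asdict(base),
                    "T": 1, "F": 1, "q": 0.0, "n_generalists": 0,
                    **cfg.params_overrides,
                }
            )
        pool = sample_pool(params, rep_seed)
        if structured:
            r1 = pool.schema.resources_in_class(classes[0])[0]
            r2 = pool.schema.resources_in_class(classes[1])[0]
        else:
            r1, r2 = 0, 1
        envs, initials, extra = [], [], []
        for a in a_values:
            kappa = make_supply(
                "pair", pool.schema, cfg.total_flux, {"resources": (r1, r2), "a": a}
            )
            envs.append(Environment(kappa=kappa, m_env=0.0, tau_R=params.tau_R))
            N0 = np.full(params.S_tot, 1.0 / params.S_tot)
            initials.append(CommunityState(N=N0, R=np.zeros(params.M)))
            extra.append({"site": f"rep{rep}", "a": a, "replicate": rep,
                          "sample_seed": rep_seed})
        tables.append(_run_batch(pool, envs, initials, cfg, extra))

    if len(tables) == 1:
        return tables[0]
    values = pd.concat([t.values for t in tables], keys=range(len(tables)))
    values.index = pd.Index(
        [f"rep{r}_{s}" for r, s in values.index], name="sample"
    )
    meta = pd.concat([t.sample_meta for t in tables]).set_index(values.index)
    return AbundanceTable(
        values=values, sample_meta=meta, species_meta=tables[0].species_meta,
        pool=tables[0].pool,
    )
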