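"""Synthetic cohorts, pedigrees and polygenic traits.

The kindred's individual-level data are not public, so every downstream stage
is exercised on generated data: plasma factor panels drawn from truncated
normals whose truncated moments match the printed per-group means/SDs, group
sizes and sex splits matching the printed stratification, an optional raw
roster carrying the six exclusion categories at their printed counts, and a
multi-generation pedigree with a generative polygenic trait model for the
variance-component statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortTable, EXCLUSION_COLUMNS, FACTOR_COLUMNS
from .kinetics import EXCLUSION_FLAGS

__all__ = [
    "FactorParams",
    "FactorDistributionSpec",
    "DEFAULT_SPEC",
    "CohortDesign",
    "DEFAULT_EXCLUSION_COUNTS",
    "sample_factors",
    "sample_composition",
    "generate_cohort",
    "PedigreeMember",
    "SyntheticPedigree",
    "generate_pedigree",
    "simulate_polygenic_trait",
]


@dataclass(frozen=True)
class FactorParams:
    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"range [{self.lo}, {self.hi}] must contain mean {self.mean}")


# Kindred-wide marginals: mean (SD) and observed range per factor.
_OVERALL = {
    "fII_uM": FactorParams(1.8, 0.4, 0.7, 2.9),
    "fV_nM": FactorParams(20.1, 6.7, 7.0, 60.0),
    "fVII_nM": FactorParams(10.0, 2.5, 4.0, 20.5),
    "fVIII_nM": FactorParams(0.8, 0.3, 0.24, 1.8),
    "fIX_nM": FactorParams(93.3, 27.0, 47.6, 225.0),
    "fX_nM": FactorParams(167.0, 38.0, 79.8, 274.0),
    "AT_uM": FactorParams(3.4, 0.6, 1.5, 5.6),
    "TFPI_nM": FactorParams(2.3, 0.6, 1.1, 5.0),
    "PC_nM": FactorParams(96.0, 38.0, 16.0, 207.0),
}

# Group-specific marginals (all-subjects rows of the printed group comparison).
_GROUP_MEANS_SD: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("pc_mutation", "yes"): {
        "fII_uM": (1.7, 0.4), "fV_nM": (19.4, 6.8), "fVII_nM": (9.9, 2.5),
        "fVIII_nM": (0.85, 0.27), "fIX_nM": (88.0, 27.0), "fX_nM": (160.0, 39.0),
        "AT_uM": (3.5, 0.6), "TFPI_nM": (2.2, 0.6), "PC_nM": (47.0, 29.0),
    },
    ("pc_mutation", "no"): {
        "fII_uM": (1.8, 0.4), "fV_nM": (20.6, 6.7), "fVII_nM": (10.1, 2.4),
        "fVIII_nM": (0.79, 0.27), "fIX_nM": (94.0, 26.0), "fX_nM": (169.0, 38.0),
        "AT_uM": (3.3, 0.6), "TFPI_nM": (2.4, 0.6), "PC_nM": (110.0, 28.0),
    },
    ("pt_g20210a", "yes"): {
        "fII_uM": (2.1, 0.4), "fV_nM": (20.3, 6.8), "fVII_nM": (10.3, 2.5),
        "fVIII_nM": (0.81, 0.26), "fIX_nM": (86.0, 27.0), "fX_nM": (178.0, 38.0),
        "AT_uM": (3.3, 0.6), "TFPI_nM": (2.5, 0.6), "PC_nM": (91.0, 37.0),
    },
    ("pt_g20210a", "no"): {
        "fII_uM": (1.7, 0.4), "fV_nM": (20.4, 6.9), "fVII_nM": (10.0, 2.5),
        "fVIII_nM": (0.80, 0.27), "fIX_nM": (94.0, 27.0), "fX_nM": (165.0, 39.0),
        "AT_uM": (3.4, 0.6), "TFPI_nM": (2.3, 0.6), "PC_nM": (100.0, 38.0),
    },
    ("thrombosis_history", "definite"): {
        "fII_uM": (2.0, 0.4), "fV_nM": (25.2, 6.7), "fVII_nM": (11.1, 2.5),
        "fVIII_nM": (1.04, 0.27), "fIX_nM": (78.0, 27.0), "fX_nM": (186.0, 39.0),
        "AT_uM": (3.3, 0.6), "TFPI_nM": (2.6, 0.6), "PC_nM": (69.0, 39.0),
    },
    ("thrombosis_history", "none"): {
        "fII_uM": (1.8, 0.4), "fV_nM": (20.1, 6.7), "fVII_nM": (10.0, 2.5),
        "fVIII_nM": (0.80, 0.27), "fIX_nM": (94.0, 27.0), "fX_nM": (167.0, 38.0),
        "AT_uM": (3.4, 0.6), "TFPI_nM": (2.3, 0.6), "PC_nM": (97.0, 38.0),
    },
}


@dataclass(frozen=True)
class FactorDistributionSpec:
    """Per-factor truncated-normal marginals with per-group overrides.

    Sampling conditions on the ``group_by`` label (default the PC mutation,
    the dominant compositional signal); when a subject additionally carries
    the prothrombin variant, the prothrombin (fII) margin is taken from the
    variant-positive row.
    """

    factors: dict[str, FactorParams] = field(default_factory=lambda: dict(_OVERALL))
    overrides: dict[tuple[str, str], dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _GROUP_MEANS_SD.items()}
    )
    group_by: str = "pc_mutation"

    def params_for(self, labels: dict[str, str] | None = None) -> dict[str, FactorParams]:
        labels = labels or {}
        out = dict(self.factors)
        key = (self.group_by, labels.get(self.group_by, ""))
        if key in self.overrides:
            for factor, (mean, sd) in self.overrides[key].items():
                out[factor] = replace(out[factor], mean=mean, sd=sd)
        if self.group_by != "pt_g20210a" and labels.get("pt_g20210a") == "yes":
            pt = self.overrides.get(("pt_g20210a", "yes"), {})
            if "fII_uM" in pt:
                mean, sd = pt["fII_uM"]
                out["fII_uM"] = replace(out["fII_uM"], mean=mean, sd=sd)
        return out


DEFAULT_SPEC = FactorDistributionSpec()

#: printed exclusion-category counts (coumadin, unknown coumadin, unconfirmed
#: self-reported DVT/PE, superficial only, insufficient sample, insufficient
#: composition) summing to 150 = 514 - 364
DEFAULT_EXCLUSION_COUNTS = dict(zip(EXCLUSION_FLAGS, (35, 5, 11, 18, 6, 75)))


@dataclass(frozen=True)
class CohortDesign:
    """Group sizes and sex splits of the generated cohort (printed defaults)."""

    n_carrier_f: int = 54
    n_carrier_m: int = 27
    n_noncarrier_f: int = 159
    n_noncarrier_m: int = 124
    pt_yes_f: int = 21
    pt_yes_m: int = 22
    pt_no: int = 292
    thrombosis_f: int = 8
    thrombosis_m: int = 5
    thrombosis_carriers: int = 8  # cases carrying the PC mutation
    factor_correlation: np.ndarray | None = None  # 9x9, factor order FACTOR_COLUMNS
    seed: int = 0

    @property
    def n_carrier(self) -> int:
        return self.n_carrier_f + self.n_carrier_m

    @property
    def n_noncarrier(self) -> int:
        return self.n_noncarrier_f + self.n_noncarrier_m

    @property
    def n_total(self) -> int:
        return self.n_carrier + self.n_noncarrier

    @property
    def n_thrombosis(self) -> int:
        return self.thrombosis_f + self.thrombosis_m

    def __post_init__(self) -> None:
        for name in (
            "n_carrier_f", "n_carrier_m", "n_noncarrier_f", "n_noncarrier_m",
            "pt_yes_f", "pt_yes_m", "pt_no", "thrombosis_f", "thrombosis_m",
            "thrombosis_carriers",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pt_yes_f + self.pt_yes_m + self.pt_no > self.n_total:
            raise ValueError("PT label counts exceed cohort size")
        if self.n_thrombosis > self.n_total or self.thrombosis_carriers > self.n_thrombosis:
            raise ValueError("inconsistent thrombosis counts")
        if self.factor_correlation is not None:
            C = np.asarray(self.factor_correlation)
            if C.shape != (len(FACTOR_COLUMNS),) * 2 or not np.allclose(C, C.T):
                raise ValueError("factor_correlation must be a symmetric 9x9 matrix")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("factor_correlation must be positive semidefinite")


# ---------------------------------------------------------------------------
# truncated-normal margins with matched truncated moments


@lru_cache(maxsize=None)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) such that the [lo, hi]-truncated normal has the
    requested mean and SD.  Falls back to the naive parameters if the target
    moments are infeasible for the window."""
    if sd == 0:
        return mean, 0.0

    def residual(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [(m - mean) / sd, (np.sqrt(v) - sd) / sd]

    sol = optimize.least_squares(residual, [mean, np.log(sd)], xtol=1e-12, ftol=1e-12)
    if not sol.success or np.linalg.norm(sol.fun) > 1e-6:
        return mean, sd
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncnorm_frozen(p: FactorParams):
    mu, sigma = _matched_truncnorm(p.mean, p.sd, p.lo, p.hi)
    a, b = (p.lo - mu) / sigma, (p.hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def sample_factors(
    spec: FactorDistributionSpec,
    labels: dict[str, str] | None,
    size: int,
    rng: np.random.Generator,
    correlation: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Draw ``size`` factor panels for one label combination.

    Margins are truncated normals (moment-matched); with a correlation matrix
    a Gaussian copula couples them while preserving every margin.
    """
    params = spec.params_for(labels)
    if any(p.sd - 0.0 < 1e-300 for p in params.values()) and correlation is not None:
        raise ValueError("correlated sampling undefined with degenerate (sd=0) margins")
    out: dict[str, np.ndarray] = {}
    if correlation is None:
        for col in FACTOR_COLUMNS:
            p = params[col]
            if p.sd == 0:
                out[col] = np.full(size, p.mean)
            else:
                out[col] = _truncnorm_frozen(p).rvs(size=size, random_state=rng)
    else:
        L = np.linalg.cholesky(correlation + 1e-12 * np.eye(len(FACTOR_COLUMNS)))
        z = rng.standard_normal((size, len(FACTOR_COLUMNS))) @ L.T
        u = stats.norm.cdf(z)
        for j, col in enumerate(FACTOR_COLUMNS):
            out[col] = _truncnorm_frozen(params[col]).ppf(u[:, j])
    return out


def sample_composition(
    spec: FactorDistributionSpec,
    labels: dict[str, str],
    rng: np.random.Generator,
    subject_id: str = "synthetic",
):
    """One :class:`~thrombogen.kinetics.PlasmaComposition` draw."""
    from .kinetics import PlasmaComposition

    draw = sample_factors(spec, labels, 1, rng)
    return PlasmaComposition(
        subject_id=subject_id,
        **{col: float(v[0]) for col, v in draw.items()},
        sex=labels.get("sex", "F"),
        age=float(labels.get("age", 45.0)),
        pc_mutation=labels.get("pc_mutation", "no"),
        pt_g20210a=labels.get("pt_g20210a", "no"),
        thrombosis_history=labels.get("thrombosis_history", "none"),
    )


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(
    design: CohortDesign = CohortDesign(),
    spec: FactorDistributionSpec = DEFAULT_SPEC,
    *,
    raw_roster: bool = False,
    exclusion_counts: dict[str, int] | None = None,
) -> CohortTable:
    """Generate a cohort with the designed group sizes and sex splits.

    With ``raw_roster=True``, additional flagged rows are appended at the
    given per-category counts (defaults to the printed counts, disjoint
    flags), yielding the pre-filtering roster.
    """
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    for pc, sex, n in (
        ("yes", "F", design.n_carrier_f),
        ("yes", "M", design.n_carrier_m),
        ("no", "F", design.n_noncarrier_f),
        ("no", "M", design.n_noncarrier_m),
    ):
        rows += [{"pc_mutation": pc, "sex": sex} for _ in range(n)]

    # thrombosis history: printed carrier share first, then non-carriers,
    # respecting the per-sex case counts
    def assign_thrombosis() -> None:
        want = {"F": design.thrombosis_f, "M": design.thrombosis_m}
        remaining_carrier = design.thrombosis_carriers
        for row in rows:
            row["thrombosis_history"] = "none"
        order = sorted(range(len(rows)), key=lambda i: (rows[i]["pc_mutation"] != "yes", i))
        for i in order:
            sex = rows[i]["sex"]
            if sum(want.values()) == 0:
                break
            is_carrier = rows[i]["pc_mutation"] == "yes"
            if is_carrier and remaining_carrier == 0:
                continue
            if not is_carrier and remaining_carrier > 0 and sum(want.values()) <= remaining_carrier:
                continue
            if want[sex] > 0:
                rows[i]["thrombosis_history"] = "definite"
                want[sex] -= 1
                if is_carrier:
                    remaining_carrier -= 1

    assign_thrombosis()

    # prothrombin variant: per-sex "yes" counts, then "no", remainder unknown
    want_yes = {"F": design.pt_yes_f, "M": design.pt_yes_m}
    idx_by_sex = {"F": [], "M": []}
    for i, row in enumerate(rows):
        idx_by_sex[row["sex"]].append(i)
    for sex, idxs in idx_by_sex.items():
        picked = rng.permutation(idxs)
        for j, i in enumerate(picked):
            rows[i]["pt_g20210a"] = "yes" if j < want_yes[sex] else "pending"
    pending = [i for i, row in enumerate(rows) if row["pt_g20210a"] == "pending"]
    for j, i in enumerate(rng.permutation(pending)):
        rows[i]["pt_g20210a"] = "no" if j < design.pt_no else "unknown"

    df_rows = []
    counter = 0
    for row in rows:
        counter += 1
        labels = dict(row)
        draw = sample_factors(spec, labels, 1, rng, design.factor_correlation)
        age = float(np.clip(rng.normal(45.0, 16.0), 18.0, 90.0))
        rec = {
            "subject_id": f"S{counter:04d}",
            **{col: float(v[0]) for col, v in draw.items()},
            "sex": row["sex"],
            "age": round(age, 1),
            "pc_mutation": row["pc_mutation"],
            "pt_g20210a": row["pt_g20210a"],
            "thrombosis_history": row["thrombosis_history"],
            **{c: False for c in EXCLUSION_COLUMNS},
        }
        df_rows.append(rec)

    if raw_roster:
        counts = exclusion_counts or DEFAULT_EXCLUSION_COUNTS
        unknown = set(counts) - set(EXCLUSION_FLAGS)
        if unknown:
            raise ValueError(f"unknown exclusion categories {sorted(unknown)}")
        for flag, n in counts.items():
            col = f"excl_{flag}"
            for _ in range(n):
                counter += 1
                draw = sample_factors(spec, None, 1, rng, design.factor_correlation)
                rec = {
                    "subject_id": f"S{counter:04d}",
                    **{c: float(v[0]) for c, v in draw.items()},
                    "sex": rng.choice(["F", "M"]),
                    "age": round(float(np.clip(rng.normal(45.0, 16.0), 18.0, 90.0)), 1),
                    "pc_mutation": rng.choice(["yes", "no"]),
                    "pt_g20210a": "unknown",
                    "thrombosis_history": "none",
                    **{c: False for c in EXCLUSION_COLUMNS},
                }
                rec[col] = True
                df_rows.append(rec)

    df = pd.DataFrame(df_rows)
    return CohortTable(df, source=f"synthetic(seed={design.seed})")


# ---------------------------------------------------------------------------
# pedigrees and polygenic traits


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father: str | None
    mother: str | None
    sex: str
    age: float
    generation: int = 0

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class SyntheticPedigree:
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m.id in seen:
                raise ValueError(f"duplicate pedigree id {m.id!r}")
            for p in (m.father, m.mother):
                if p is not None and p not in seen:
                    raise ValueError(f"member {m.id!r}: parent {p!r} does not precede it")
            seen.add(m.id)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def n_generations(self) -> int:
        return max(m.generation for m in self.members) if self.members else 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [m.id for m in self.members],
                "father": [m.father or "" for m in self.members],
                "mother": [m.mother or "" for m in self.members],
                "sex": [m.sex for m in self.members],
                "age": [m.age for m in self.members],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SyntheticPedigree":
        members = []
        for row in df.itertuples(index=False):
            father = str(row.father) if str(getattr(row, "father", "") or "") not in ("", "nan") else None
            mother = str(row.mother) if str(getattr(row, "mother", "") or "") not in ("", "nan") else None
            members.append(
                PedigreeMember(str(row.id), father, mother, str(getattr(row, "sex", "F")),
                               float(getattr(row, "age", 45.0)))
            )
        return cls(members)


def generate_pedigree(
    founder_pairs: int,
    generations: int,
    mean_offspring: float = 3.0,
    seed: int = 0,
) -> SyntheticPedigree:
    """Forward-simulate an acyclic multi-generation pedigree.

    Each founding couple has a Poisson number of children (minimum 1); each
    child who is not in the last generation marries a married-in founder, and
    the new couple reproduces in turn.  Every non-founder therefore has two
    in-pedigree parents.
    """
    if founder_pairs < 1 or generations < 0:
        raise ValueError("founder_pairs >= 1 and generations >= 0 required")
    rng = np.random.default_rng(seed)
    members: list[PedigreeMember] = []
    counter = 0

    def new_member(father, mother, sex, generation) -> PedigreeMember:
        nonlocal counter
        counter += 1
        age = float(np.clip(20.0 + 25.0 * (generations - generation) + rng.normal(0, 3), 18, 100))
        m = PedigreeMember(f"P{counter:04d}", father, mother, sex, round(age, 1), generation)
        members.append(m)
        return m

    couples = []
    for _ in range(founder_pairs):
        f = new_member(None, None, "M", 0)
        m = new_member(None, None, "F", 0)
        couples.append((f, m))

    for gen in range(1, generations + 1):
        next_couples = []
        for father, mother in couples:
            n_kids = max(1, int(rng.poisson(mean_offspring)))
            for _ in range(n_kids):
                sex = str(rng.choice(["M", "F"]))
                child = new_member(father.id, mother.id, sex, gen)
                if gen < generations:
                    spouse = new_member(None, None, "F" if sex == "M" else "M", gen)
                    next_couples.append((child, spouse) if sex == "M" else (spouse, child))
        couples = next_couples
    return SyntheticPedigree(members)


def trim_pedigree(pedigree: SyntheticPedigree, n: int) -> SyntheticPedigree:
    """First ``n`` members in generation order (a parent-closed prefix)."""
    if n > len(pedigree):
        raise ValueError(f"pedigree has only {len(pedigree)} members, need {n}")
    return SyntheticPedigree(list(pedigree.members[:n]))


def relabel_pedigree(pedigree: SyntheticPedigree, new_ids: list[str]) -> SyntheticPedigree:
    """Rename members (in order), rewriting parent references."""
    if len(new_ids) != len(pedigree):
        raise ValueError("need exactly one new id per member")
    mapping = {m.id: new for m, new in zip(pedigree.members, new_ids)}
    return SyntheticPedigree(
        [
            replace(
                m,
                id=mapping[m.id],
                father=None if m.father is None else mapping[m.father],
                mother=None if m.mother is None else mapping[m.mother],
            )
            for m in pedigree.members
        ]
    )


def pedigree_for_cohort(
    cohort: CohortTable,
    generations: int = 3,
    mean_offspring: float = 3.0,
    seed: int = 0,
) -> SyntheticPedigree:
    """A pedigree sized and relabeled to match the cohort's subject ids."""
    n = len(cohort)
    founder_pairs = 2
    for _ in range(20):
        ped = generate_pedigree(founder_pairs, generations, mean_offspring, seed)
        if len(ped) >= n:
            return relabel_pedigree(trim_pedigree(ped, n), list(cohort.df["subject_id"]))
        founder_pairs *= 2
    raise RuntimeError("could not grow a pedigree large enough for the cohort")


def simulate_polygenic_trait(
    pedigree: SyntheticPedigree,
    h2: float,
    total_variance: float = 1.0,
    *,
    beta0: float = 0.0,
    beta_age: float = 0.0,
    beta_sex: float = 0.0,
    beta_group: float = 0.0,
    group: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generative polygenic trait: ``y = Xb + g + e``.

    Founder genetic values are N(0, sigma2_g); each child's is the parental
    midpoint plus segregation noise of variance sigma2_g/2, so cov(g) = 2 Phi
    sigma2_g for a non-inbred pedigree.  ``e`` is iid N(0, sigma2_e) with
    sigma2_g = h2 * total_variance and sigma2_e = (1 - h2) * total_variance.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must be in [0, 1]")
    if total_variance < 0:
        raise ValueError("total_variance must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s2g = h2 * total_variance
    s2e = (1.0 - h2) * total_variance
    g: dict[str, float] = {}
    for m in pedigree.members:
        if m.is_founder:
            g[m.id] = rng.normal(0.0, np.sqrt(s2g)) if s2g > 0 else 0.0
        else:
            mid = 0.5 * (g[m.father] + g[m.mother])
            g[m.id] = mid + (rng.normal(0.0, np.sqrt(s2g / 2.0)) if s2g > 0 else 0.0)
    n = len(pedigree)
    group_arr = np.zeros(n) if group is None else np.asarray(group, dtype=float)
    if group_arr.shape != (n,):
        raise ValueError("group must align with the pedigree")
    fixed = np.array(
        [
            beta0
            + beta_age * m.age
            + beta_sex * (1.0 if m.sex == "M" else 0.0)
            for m in pedigree.members
        ]
    )
    fixed += beta_group * group_arr
    e = rng.normal(0.0, np.sqrt(s2e), size=n) if s2e > 0 else np.zeros(n)
    return fixed + np.array([g[m.id] for m in pedigree.members]) + e
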