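"""Knockout metabolite-profile phenotypes.

Each knockout strain's compound table (already-quantified amounts of the
four core azaphilone pigments and the two acetyl-monasfluol shunt products)
is compared against the wild type and classified into one of four
categories, applied first-match-wins:

abolished   all core pigments absent and no shunt product present
shunt       any shunt (derailment) product present
ratio_shift all core pigments present but some pairwise core ratio deviates
            more than 2-fold from the wild type
unchanged   everything else (every core amount within 2-fold, ratios stable)

The underlying experimental evidence is qualitative (HPLC traces, colony
color); the 5% absence floor and the 2-fold tolerances are explicit
quantifications of that reading and are configurable.  All thresholds are
relative, so the categories are invariant under a common rescaling of the
profiles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd


class KnockoutError(ValueError):
    pass


class KnockoutCategory(enum.Enum):
    ABOLISHED = "abolished"
    SHUNT = "shunt"
    RATIO_SHIFT = "ratio_shift"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class Compound:
    compound_id: int
    name: str
    role: str  # "core" or "shunt"


#: compounds 1-4 are the canonical pigments, 5-6 the derailment products
DEFAULT_REGISTRY: tuple[Compound, ...] = (
    Compound(1, "monascin", "core"),
    Compound(2, "rubropunctatin", "core"),
    Compound(3, "ankaflavin", "core"),
    Compound(4, "monascorubrin", "core"),
    Compound(5, "acetyl-monasfluol A", "shunt"),
    Compound(6, "acetyl-monasfluol B", "shunt"),
)


@dataclass(frozen=True)
class KnockoutThresholds:
    """absence_frac: core compound 'absent' below this fraction of wild type;
    fold_tol: amounts/ratios within this factor (inclusive) count as stable;
    shunt_floor_frac: shunt 'present' above this fraction of the mean
    wild-type core amount (relative so categories are scale invariant)."""

    absence_frac: float = 0.05
    fold_tol: float = 2.0
    shunt_floor_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.absence_frac < 1) or self.fold_tol < 1 or self.shunt_floor_frac <= 0:
            raise KnockoutError("invalid knockout thresholds")


DEFAULT_KO_THRESHOLDS = KnockoutThresholds()


@dataclass
class MetaboliteProfile:
    strain: str
    amounts: dict[int, float]
    registry: tuple[Compound, ...] = DEFAULT_REGISTRY

    def __post_init__(self) -> None:
        for cid, amount in self.amounts.items():
            if amount < 0:
                raise KnockoutError(f"strain {self.strain}: negative amount for compound {cid}")

    def amount(self, compound_id: int) -> float:
        return float(self.amounts.get(compound_id, 0.0))

    def core_ids(self) -> list[int]:
        return [c.compound_id for c in self.registry if c.role == "core"]

    def shunt_ids(self) -> list[int]:
        return [c.compound_id for c in self.registry if c.role == "shunt"]


@dataclass
class KnockoutPhenotype:
    strain: str
    category: KnockoutCategory
    folds: dict[int, float] = field(default_factory=dict)  # mutant / wild type per compound


def _within_fold(x: float, y: float, tol: float) -> bool:
    """True when x and y differ by at most a factor tol (inclusive)."""
    if x == 0 and y == 0:
        return True
    if x == 0 or y == 0:
        return False
    r = x / y
    return (1.0 / tol) - 1e-12 <= r <= tol + 1e-12


def compare_profiles(wt: MetaboliteProfile, mutant: MetaboliteProfile,
                     thresholds: KnockoutThresholds = DEFAULT_KO_THRESHOLDS) -> KnockoutPhenotype:
    """Classify one mutant profile against the wild type (first match wins)."""
    if wt.registry != mutant.registry:
        raise KnockoutError("wild-type and mutant profiles use different compound registries")
    core = wt.core_ids()
    shunt = wt.shunt_ids()
    for cid in core:
        if wt.amount(cid) <= 0:
            raise KnockoutError(f"wild-type amount of core compound {cid} must be positive")

    folds = {
        cid: (mutant.amount(cid) / wt.amount(cid)) if wt.amount(cid) > 0 else float("inf")
        for cid in core
    }
    for cid in shunt:
        w, m = wt.amount(cid), mutant.amount(cid)
        if w > 0:
            folds[cid] = m / w
        else:
            # wild type lacks the shunt product: a gain is infinite, no
            # product on either side leaves the fold undefined
            folds[cid] = float("inf") if m > 0 else float("nan")

    mean_wt_core = sum(wt.amount(c) for c in core) / len(core)
    shunt_floor = thresholds.shunt_floor_frac * mean_wt_core
    core_absent = [mutant.amount(c) < thresholds.absence_frac * wt.amount(c) for c in core]
    shunt_present = [mutant.amount(c) > shunt_floor for c in shunt]

    if all(core_absent) and not any(shunt_present):
        cat = KnockoutCategory.ABOLISHED
    elif any(shunt_present):
        cat = KnockoutCategory.SHUNT
    elif not any(core_absent) and _ratio_shifted(wt, mutant, core, thresholds.fold_tol):
        cat = KnockoutCategory.RATIO_SHIFT
    else:
        cat = KnockoutCategory.UNCHANGED
    return KnockoutPhenotype(strain=mutant.strain, category=cat, folds=folds)


def _ratio_shifted(wt, mutant, core, tol) -> bool:
    for i, ci in enumerate(core):
        for cj in core[i + 1:]:
            r_wt = wt.amount(ci) / wt.amount(cj)
            if mutant.amount(cj) == 0:
                return True
            r_m = mutant.amount(ci) / mutant.amount(cj)
            if not _within_fold(r_m, r_wt, tol):
                return True
    return False


def evaluate_knockout_panel(wt: MetaboliteProfile, mutants: list[MetaboliteProfile],
                            thresholds: KnockoutThresholds = DEFAULT_KO_THRESHOLDS
                            ) -> dict[str, KnockoutPhenotype]:
    """Phenotype per mutant strain, keyed by strain name."""
    return {m.strain: compare_profiles(wt, m, thresholds) for m in mutants}


def load_profiles(path, registry: tuple[Compound, ...] = DEFAULT_REGISTRY
                  ) -> dict[str, MetaboliteProfile]:
    """Read a strain,compound,amount CSV into per-strain profiles."""
    df = pd.read_csv(path, dtype={"strain": str})
    for col in ("strain", "compound", "amount"):
        if col not in df.columns:
            raise KnockoutError(f"profiles table lacks column {col!r}")
    out: dict[str, MetaboliteProfile] = {}
    for strain, sub in df.groupby("strain", sort=False):
        amounts = {int(r.compound): float(r.amount) for r in sub.itertuples()}
        out[str(strain)] = MetaboliteProfile(strain=str(strain), amounts=amounts,
                                             registry=registry)
    return out


def write_phenotypes(phenotypes: dict[str, KnockoutPhenotype], path) -> None:
    rows = []
    for strain, ph in phenotypes.items():
        row = {"strain": strain, "category": ph.category.value}
        for cid, f in sorted(ph.folds.items()):
            row[f"fold_{cid}"] = f
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
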