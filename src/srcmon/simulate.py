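"""Generative simulator of the two-group judgment-of-source experiment.

The simulated study follows the schema-based source-monitoring paradigm:
participants study 32 schema-expected and 32 schema-unexpected source-item
pairs (scenes "kitchen" and "bathroom" as sources), judge the likelihood of
later remembering each item's source (JOS, 0-100), choose pairs for restudy
(at most 32; the remainder is substituted 50/50 from unchosen expected and
unexpected pairs), restudy 32 pairs, and complete a 3AFC source-monitoring
test over the 64 studied items plus 32 distractors.  The *immediate* group
makes JOSs and restudy choices at study; the *delayed* group first attempts
a 2AFC source attribution for every studied item and only then judges and
chooses.

Generative components:

- test responses come from the two-high-threshold MPT trees with individual
  parameters drawn from a probit-scale normal around group-level means
  (heterogeneity SD on the probit scale);
- 2AFC attributions use a one-high-threshold retrieval-plus-guessing form:
  P(correct | expected) = a_E + (1 - a_E) g2afc and
  P(correct | unexpected) = a_U + (1 - a_U)(1 - g2afc), a simulator
  convention for a task to which no measurement model is fitted;
- JOSs follow a linear model with a group-specific expectancy effect
  (positive for the immediate group, weakly negative for the delayed group),
  an attribution-accuracy effect in the delayed group, a participant random
  intercept, and residual noise, rounded and clamped to 0-100;
- restudy choices are sequential Bernoulli draws with probability decreasing
  logistically in JOS, stopping once the cap is hit (the on-screen tracker),
  which yields the negative JOS-restudy association;
- an optional restudy boost adds a probit shift to the item/source-memory
  parameters of restudied items at test (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from srcmon.io import TRIAL_COLUMNS
from srcmon.mpt import (
    FREE_PARAM_NAMES,
    FrequencyTable,
    MPTDomainError,
    Restriction,
    _free_to_probs,
)

GROUPS = ("immediate", "delayed")
SCENES = ("kitchen", "bathroom")


def calibrate_2afc(
    p_correct_expected: float, p_correct_unexpected: float, a_expected: float = 0.20
) -> tuple[float, float, float]:
    """Solve the 2AFC retrieval-plus-guessing equations for given accuracy targets.

    Given target correct-attribution rates and a fixed retrieval probability
    for expected pairs, returns ``(a_expected, a_unexpected, g2afc)`` such
    that the closed-form accuracies match the targets exactly.
    """
    g2 = (p_correct_expected - a_expected) / (1.0 - a_expected)
    if not (0.0 <= g2 <= 1.0):
        raise MPTDomainError("no valid guessing rate for these targets")
    denom = g2
    a_u = (p_correct_unexpected - (1.0 - g2)) / denom if denom > 0 else 0.0
    if not (0.0 <= a_u <= 1.0):
        raise MPTDomainError("no valid unexpected retrieval rate for these targets")
    return a_expected, a_u, g2


# defaults solved from the reference 2AFC accuracies 1732/2304 and 1406/2304
_A_E_DEFAULT, _A_U_DEFAULT, _G2_DEFAULT = calibrate_2afc(
    1732 / 2304, 1406 / 2304, 0.20
)


def _default_group_means() -> dict[str, dict[str, float]]:
    return {
        "immediate": {"D_E": 0.71, "D_U": 0.73, "d_E": 0.48, "d_U": 0.83,
                      "b": 0.33, "g": 0.75},
        "delayed": {"D_E": 0.78, "D_U": 0.83, "d_E": 0.31, "d_U": 0.64,
                    "b": 0.39, "g": 0.61},
    }


def _default_jos_expectancy() -> dict[str, float]:
    # mean JOS difference (expected - unexpected) per group
    return {"immediate": 6.5, "delayed": -1.0}


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions of the simulated experiment (defaults = full scale)."""

    n_participants: int = 72           # per group
    n_items_per_type: int = 32         # expected / unexpected / new
    group_means: dict[str, dict[str, float]] = field(
        default_factory=_default_group_means
    )
    heterogeneity_sd: float = 0.4      # probit-scale SD of individual parameters
    restriction: Restriction = "D_N=D_U"
    # 2AFC source attribution (delayed group)
    afc_retrieval_expected: float = _A_E_DEFAULT
    afc_retrieval_unexpected: float = _A_U_DEFAULT
    afc_guessing: float = _G2_DEFAULT
    # JOS linear model
    jos_intercept: float = 50.0
    jos_expectancy_effect: dict[str, float] = field(
        default_factory=_default_jos_expectancy
    )
    jos_accuracy_effect: float = 15.0  # delayed group: correct - incorrect 2AFC
    jos_participant_sd: float = 15.0
    jos_residual_sd: float = 18.0
    # restudy policy
    restudy_cap: int = 32
    choice_midpoint: float = 50.0      # JOS at which P(choose) = .5
    choice_scale: float = 15.0         # logistic scale; choice prob falls with JOS
    restudy_boost: float = 0.0         # probit shift on D and d for restudied items

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_items_per_type < 1:
            raise MPTDomainError("participants and items must be >= 1")
        if 2 * self.n_items_per_type < self.restudy_cap:
            raise MPTDomainError(
                "fewer selectable pairs than the restudy cap; "
                "increase n_items_per_type or lower restudy_cap"
            )
        for grp in GROUPS:
            if grp not in self.group_means:
                raise MPTDomainError(f"group_means missing group {grp!r}")
            for name in FREE_PARAM_NAMES:
                v = self.group_means[grp].get(name)
                if v is None or not (0.0 < v < 1.0):
                    raise MPTDomainError(
                        f"group mean {name} for {grp!r} must lie in (0, 1)"
                    )


@dataclass(frozen=True)
class ExclusionReport:
    """Participants flagged by dataset validation, with reasons."""

    exclusions: tuple[tuple[str, str], ...]

    @property
    def flagged_ids(self) -> tuple[str, ...]:
        return tuple(sorted({pid for pid, _ in self.exclusions}))

    def reasons_for(self, participant: str) -> list[str]:
        return [r for pid, r in self.exclusions if pid == participant]


def _simulate_participant(
    cfg: ExperimentConfig, group: str, pid: str, rng: np.random.Generator
) -> list[dict]:
    n_item = cfg.n_items_per_type
    mean_vec = np.array([cfg.group_means[group][p] for p in FREE_PARAM_NAMES])
    eta = ndtri(mean_vec) + cfg.heterogeneity_sd * rng.standard_normal(6)

    # items: 0..n-1 expected, n..2n-1 unexpected, 2n..3n-1 new
    expectancy = np.array(
        ["expected"] * n_item + ["unexpected"] * n_item + ["new"] * n_item
    )
    expected_scene = np.array([SCENES[i % 2] for i in range(3 * n_item)])
    other = {"kitchen": "bathroom", "bathroom": "kitchen"}
    true_scene = np.where(
        expectancy == "expected",
        expected_scene,
        np.where(
            expectancy == "unexpected",
            [other[s] for s in expected_scene],
            "none",
        ),
    )
    item_ids = np.array([f"i{j:03d}" for j in range(3 * n_item)])
    studied = np.arange(2 * n_item)

    u_i = cfg.jos_participant_sd * rng.standard_normal()
    exp_code = np.where(expectancy[studied] == "expected", 0.5, -0.5)

    rows: list[dict] = []
    base = dict(participant=pid, group=group)

    # --- study phase (randomized presentation order)
    study_order = rng.permutation(studied)
    if group == "immediate":
        jos_raw = (
            cfg.jos_intercept
            + cfg.jos_expectancy_effect[group] * exp_code
            + u_i
            + cfg.jos_residual_sd * rng.standard_normal(2 * n_item)
        )
        jos = np.clip(np.round(jos_raw), 0, 100).astype(int)
        choice = _sequential_choices(cfg, jos[study_order], rng)
        choice_by_item = np.full(2 * n_item, np.nan)
        choice_by_item[study_order] = choice
        for j in study_order:
            rows.append(
                {**base, "phase": "study", "item": item_ids[j],
                 "source": true_scene[j], "expectancy": expectancy[j],
                 "response": np.nan, "jos": int(jos[j]),
                 "restudy_choice": choice_by_item[j], "restudied": np.nan}
            )
        afc_correct = None
    else:
        for j in study_order:
            rows.append(
                {**base, "phase": "study", "item": item_ids[j],
                 "source": true_scene[j], "expectancy": expectancy[j],
                 "response": np.nan, "jos": np.nan, "restudy_choice": np.nan,
                 "restudied": np.nan}
            )
        # --- delayed-judgment phase: 2AFC attribution, then JOS + choice
        judge_order = rng.permutation(studied)
        p_correct = np.where(
            expectancy[studied] == "expected",
            cfg.afc_retrieval_expected
            + (1 - cfg.afc_retrieval_expected) * cfg.afc_guessing,
            cfg.afc_retrieval_unexpected
            + (1 - cfg.afc_retrieval_unexpected) * (1 - cfg.afc_guessing),
        )
        afc_correct = rng.random(2 * n_item) < p_correct
        acc_code = np.where(afc_correct, 0.5, -0.5)
        jos_raw = (
            cfg.jos_intercept
            + cfg.jos_expectancy_effect[group] * exp_code
            + cfg.jos_accuracy_effect * acc_code
            + u_i
            + cfg.jos_residual_sd * rng.standard_normal(2 * n_item)
        )
        jos = np.clip(np.round(jos_raw), 0, 100).astype(int)
        choice = _sequential_choices(cfg, jos[judge_order], rng)
        choice_by_item = np.full(2 * n_item, np.nan)
        choice_by_item[judge_order] = choice
        attribution = np.where(
            afc_correct == (expectancy[studied] == "expected"),
            "expected",
            "unexpected",
        )
        for j in judge_order:
            rows.append(
                {**base, "phase": "delayed_judgment", "item": item_ids[j],
                 "source": true_scene[j], "expectancy": expectancy[j],
                 "response": attribution[j], "jos": int(jos[j]),
                 "restudy_choice": choice_by_item[j], "restudied": np.nan}
            )

    # --- restudy phase: honored choices plus 50/50 substitution
    chosen = np.flatnonzero(choice_by_item == 1.0)
    restudied = _apply_substitution(cfg, chosen, n_item, rng)
    for j in rng.permutation(restudied):
        rows.append(
            {**base, "phase": "restudy", "item": item_ids[j],
             "source": true_scene[j], "expectancy": expectancy[j],
             "response": np.nan, "jos": np.nan, "restudy_choice": np.nan, "restudied": np.nan}
        )

    # --- test phase: 3AFC from the MPT trees, restudy boost applied
    restudied_mask = np.zeros(3 * n_item, bool)
    restudied_mask[restudied] = True
    boost = np.zeros((3 * n_item, 6))
    boost[restudied_mask, 0:4] = cfg.restudy_boost  # D_E, D_U, d_E, d_U
    test_order = rng.permutation(3 * n_item)
    row_of = {"expected": 0, "unexpected": 1, "new": 2}
    for j in test_order:
        theta_j = _probit_to_unit(eta + boost[j])
        P = _free_to_probs(theta_j, cfg.restriction)
        r = rng.choice(3, p=P[row_of[expectancy[j]]])
        rows.append(
            {**base, "phase": "test", "item": item_ids[j],
             "source": true_scene[j], "expectancy": expectancy[j],
             "response": ("expected", "unexpected", "new")[r], "jos": np.nan,
             "restudy_choice": np.nan, "restudied": int(restudied_mask[j])}
        )
    return rows


def _probit_to_unit(eta: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(eta)


def _sequential_choices(
    cfg: ExperimentConfig, jos_in_order: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli restudy choices in presentation order until the cap.

    Returns, per trial in order: 1 chosen, 0 declined, NaN not offered
    (the tracker had already reached the cap).
    """
    out = np.full(jos_in_order.size, np.nan)
    n_chosen = 0
    p = expit((cfg.choice_midpoint - jos_in_order) / cfg.choice_scale)
    for t in range(jos_in_order.size):
        if n_chosen >= cfg.restudy_cap:
            break
        out[t] = float(rng.random() < p[t])
        n_chosen += int(out[t])
    return out


def _apply_substitution(
    cfg: ExperimentConfig, chosen: np.ndarray, n_item: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill up to the cap with a random 50/50 expected/unexpected selection."""
    need = cfg.restudy_cap - chosen.size
    if need <= 0:
        return chosen[: cfg.restudy_cap]
    unchosen_exp = np.setdiff1d(np.arange(n_item), chosen)
    unchosen_unexp = np.setdiff1d(np.arange(n_item, 2 * n_item), chosen)
    n_exp = need // 2
    n_unexp = need - n_exp
    if need % 2 == 1 and rng.random() < 0.5:
        n_exp, n_unexp = n_unexp, n_exp
    n_exp = min(n_exp, unchosen_exp.size)
    n_unexp = min(need - n_exp, unchosen_unexp.size)
    n_exp = need - n_unexp  # spill over if one side ran short
    picks = np.concatenate(
        [
            rng.choice(unchosen_exp, size=n_exp, replace=False),
            rng.choice(unchosen_unexp, size=n_unexp, replace=False),
        ]
    )
    return np.concatenate([chosen, picks])


def simulate_experiment(
    config: ExperimentConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate the full two-group experiment as a trial-record DataFrame.

    Deterministic given ``seed``: the same seed and config reproduce the
    record stream bit for bit.
    """
    cfg = config or ExperimentConfig()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for group in GROUPS:
        for i in range(cfg.n_participants):
            pid = f"{group[:3]}{i:03d}"
            rows.extend(_simulate_participant(cfg, group, pid, rng))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@dataclass(frozen=True)
class AggregatedFrequencies:
    """Group-level and per-participant frequency tables from trial records."""

    group_3afc: dict[str, FrequencyTable]
    group_2afc: dict[str, FrequencyTable]
    participant_3afc: dict[str, list[FrequencyTable]]


def _tabulate_3afc(test: pd.DataFrame, label: str) -> FrequencyTable:
    counts = np.zeros((3, 3), dtype=np.int64)
    types = ("expected", "unexpected", "new")
    for t, ttype in enumerate(types):
        sub = test[test["expectancy"] == ttype]
        for r, resp in enumerate(types):
            counts[t, r] = int((sub["response"] == resp).sum())
    return FrequencyTable(counts, label=label, task="3afc")


def aggregate_frequencies(trials: pd.DataFrame) -> AggregatedFrequencies:
    """Aggregate trial records into 3AFC / 2AFC frequency tables.

    Per group: one aggregate 3x3 table from the test phase and (for groups
    with a delayed-judgment phase) one aggregate 2x2 attribution table;
    per-participant 3x3 tables are returned for hierarchical fitting.
    """
    known = {"study", "delayed_judgment", "restudy", "test"}
    unknown = set(trials["phase"].unique()) - known
    if unknown:
        raise MPTDomainError(f"records with unknown phase(s): {sorted(unknown)}")
    group_3afc: dict[str, FrequencyTable] = {}
    group_2afc: dict[str, FrequencyTable] = {}
    participant_3afc: dict[str, list[FrequencyTable]] = {}
    for group, gtrials in trials.groupby("group", sort=True):
        test = gtrials[gtrials["phase"] == "test"]
        if len(test):
            group_3afc[group] = _tabulate_3afc(test, f"{group}_3afc")
            participant_3afc[group] = [
                _tabulate_3afc(ptest, f"{group}_{pid}")
                for pid, ptest in test.groupby("participant", sort=True)
            ]
        judge = gtrials[gtrials["phase"] == "delayed_judgment"]
        if len(judge):
            counts = np.zeros((2, 2), dtype=np.int64)
            for t, ttype in enumerate(("expected", "unexpected")):
                sub = judge[judge["expectancy"] == ttype]
                for r, resp in enumerate(("expected", "unexpected")):
                    counts[t, r] = int((sub["response"] == resp).sum())
            group_2afc[group] = FrequencyTable(
                counts, label=f"{group}_2afc", task="2afc"
            )
    return AggregatedFrequencies(group_3afc, group_2afc, participant_3afc)


def validate_dataset(trials: pd.DataFrame) -> ExclusionReport:
    """Flag participants with zero restudy choices or an undefined gamma.

    A participant who chooses no pairs at all mirrors the preregistered
    exclusion rule; a participant whose JOS-choice pairs yield no concordant
    or discordant pairs (e.g. all choices identical) has an undefined gamma
    and must be excluded listwise from gamma analyses.
    """
    from srcmon.behavioral import goodman_kruskal_gamma

    flags: list[tuple[str, str]] = []
    judged = trials[trials["phase"].isin(["study", "delayed_judgment"])]
    judged = judged[judged["restudy_choice"].notna()]
    for pid, sub in trials.groupby("participant", sort=True):
        psub = judged[judged["participant"] == pid]
        if len(psub) == 0:
            continue
        choices = psub["restudy_choice"].astype(float).to_numpy()
        if choices.sum() == 0:
            flags.append((pid, "no restudy choices"))
        jos = psub["jos"].astype(float).to_numpy()
        if len(psub) >= 2:
            result = goodman_kruskal_gamma(jos, choices)
            if not result.defined:
                flags.append((pid, "undefined gamma (no untied JOS-choice pairs)"))
    return ExclusionReport(tuple(flags))
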