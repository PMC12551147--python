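"""The iterative design campaign: train, score the space, select, measure.

One active-learning round trains the cross-validated ensemble on the current
activity table, scores the full enumerated space, and assembles a candidate
batch that balances exploitation and diversity: the top-scoring unseen
peptides, representatives of k-means clusters computed in descriptor space
over the top-scoring pool, and uniform random draws.  Measured candidates
are appended to the training table and the cycle repeats; across rounds the
pooled out-of-fold correlation is tracked as the campaign's accuracy metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .activity import ActivityTable
from .analysis import dipeptide_adjacency, position_frequency_matrix
from .descriptors import DescriptorScale, encode_table, load_scales
from .ml import CVResult, ModelConfig, predict_space, train_cv
from .rna_energy import DEFAULT_MODEL, RNAEnergyModel, energies_for_peptides
from .sequence_space import AMINO_ACIDS, CodonUsageTable, enumerate_tetrapeptides


class CapacityError(RuntimeError):
    """The unseen design space cannot fill the requested batch."""


@dataclass(frozen=True)
class SelectionPolicy:
    """How a candidate batch is assembled from full-space predictions.

    ``n_top`` exploitation picks, ``n_cluster_reps`` diversity picks (one per
    k-means cluster over the descriptor features of the top ``pool_size``
    predictions), ``n_random`` uniform draws; the three strata must sum to
    ``batch_size``.  Previously measured peptides are always excluded first.
    """

    pool_size: int = 5000
    batch_size: int = 50
    n_top: int = 25
    n_cluster_reps: int = 15
    n_random: int = 10
    k_clusters: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_top + self.n_cluster_reps + self.n_random != self.batch_size:
            raise ValueError("n_top + n_cluster_reps + n_random must equal batch_size")
        if self.pool_size < self.batch_size:
            raise ValueError("pool_size must be >= batch_size")
        if self.n_cluster_reps > 0 and self.k_clusters < self.n_cluster_reps:
            raise ValueError("k_clusters must be >= n_cluster_reps")


@dataclass
class DesignContext:
    """Precomputed feature matrix over the enumerated design space.

    Holds the peptide list (lexicographic), the (n, 157) feature matrix with
    canonical column names, and the row lookup; built once per campaign so
    scoring 160,000 peptides per round costs only a model predict.
    """

    peptides: list[str]
    X: pd.DataFrame
    scales: dict[str, DescriptorScale]
    codon_table: CodonUsageTable
    energy_model: RNAEnergyModel
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {p: i for i, p in enumerate(self.peptides)}

    @classmethod
    def build(
        cls,
        alphabet: str = AMINO_ACIDS,
        scales: Optional[dict[str, DescriptorScale]] = None,
        codon_table: Optional[CodonUsageTable] = None,
        energy_model: RNAEnergyModel = DEFAULT_MODEL,
        dtype=np.float32,
    ) -> "DesignContext":
        scales = scales if scales is not None else load_scales()
        codon_table = codon_table if codon_table is not None else CodonUsageTable.load()
        peptides = enumerate_tetrapeptides(alphabet=alphabet)
        energies = energies_for_peptides(peptides, codon_table, energy_model)
        X = encode_table(peptides, scales, energies, dtype=dtype)
        return cls(
            peptides=peptides,
            X=X,
            scales=scales,
            codon_table=codon_table,
            energy_model=energy_model,
        )

    @property
    def descriptor_columns(self) -> list[str]:
        return [c for c in self.X.columns if c != "energy"]

    def rows_for(self, peptides: Sequence[str]) -> pd.DataFrame:
        try:
            idx = [self.index[p] for p in peptides]
        except KeyError as exc:
            raise KeyError(f"peptide {exc.args[0]!r} outside the design space") from None
        return self.X.iloc[idx].reset_index(drop=True)


def select_candidates(
    peptides: Sequence[str],
    predictions: np.ndarray,
    features: np.ndarray,
    policy: SelectionPolicy,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[str]:
    """Assemble a candidate batch of exactly ``policy.batch_size`` peptides.

    Ranking is by descending prediction with lexicographic tie-break.  Any
    stratum that cannot be filled (too few clusters, exhausted pool) falls
    back to the next-best-ranked unseen peptides so the batch size contract
    always holds; an unseen space smaller than the batch raises
    :class:`CapacityError`.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (len(peptides),):
        raise ValueError("predictions must cover the enumerated space")
    eligible = [i for i, p in enumerate(peptides) if p not in exclude]
    if len(eligible) < policy.batch_size:
        raise CapacityError(
            f"only {len(eligible)} unseen peptides for a batch of {policy.batch_size}"
        )
    order = sorted(eligible, key=lambda i: (-predictions[i], peptides[i]))

    selected: list[int] = list(order[: policy.n_top])
    taken = set(selected)

    if policy.n_cluster_reps > 0:
        pool = order[: policy.pool_size]
        k = min(policy.k_clusters, len(pool))
        Xp = StandardScaler().fit_transform(np.asarray(features)[pool])
        labels = KMeans(
            n_clusters=k, n_init=3, random_state=policy.seed
        ).fit_predict(Xp)
        # clusters ranked by their best member; one rep each, best first
        by_cluster: dict[int, list[int]] = {}
        for row, lab in zip(pool, labels):
            by_cluster.setdefault(int(lab), []).append(row)
        cluster_order = sorted(
            by_cluster,
            key=lambda lab: (-max(predictions[r] for r in by_cluster[lab]), lab),
        )
        reps = 0
        for lab in cluster_order:
            if reps == policy.n_cluster_reps:
                break
            for row in by_cluster[lab]:  # pool order is already by rank
                if row not in taken:
                    selected.append(row)
                    taken.add(row)
                    reps += 1
                    break

    if policy.n_random > 0:
        rng = np.random.default_rng(policy.seed)
        remaining = [i for i in order if i not in taken]
        n_rand = min(policy.n_random, len(remaining))
        for j in rng.choice(len(remaining), size=n_rand, replace=False):
            selected.append(remaining[j])
            taken.add(remaining[j])

    for i in order:  # fallback fill keeps the size contract
        if len(selected) == policy.batch_size:
            break
        if i not in taken:
            selected.append(i)
            taken.add(i)
    return [peptides[i] for i in selected[: policy.batch_size]]


@dataclass
class RoundState:
    """State after one campaign round."""

    round_index: int
    training: ActivityTable
    cv: Optional[CVResult]
    candidates: list[str]
    candidate_predictions: np.ndarray
    r_history: list[float]
    top100: list[str] = field(default_factory=list)


@dataclass
class CampaignHistory:
    rounds: list[RoundState]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": [s.round_index for s in self.rounds],
                "n_training": [
                    len(s.cv.oof_predictions) if s.cv is not None else len(s.training)
                    for s in self.rounds
                ],
                "pooled_r": [
                    s.cv.pooled_r if s.cv is not None else float("nan")
                    for s in self.rounds
                ],
                "pooled_rmse": [
                    s.cv.pooled_rmse if s.cv is not None else float("nan")
                    for s in self.rounds
                ],
                "batch_size": [len(s.candidates) for s in self.rounds],
            }
        )

    def top100_logos(self) -> dict[int, pd.DataFrame]:
        return {
            s.round_index: position_frequency_matrix(s.top100).freqs
            for s in self.rounds
            if s.top100
        }

    def top100_adjacency(self) -> dict[int, pd.DataFrame]:
        return {
            s.round_index: dipeptide_adjacency(s.top100)
            for s in self.rounds
            if s.top100
        }


Oracle = Callable[..., ActivityTable]


class TableOracle:
    """Oracle backed by a measured-results table (e.g. a lab CSV).

    Satisfies the same contract as the synthetic oracle so experiment files
    and simulations are interchangeable in :func:`run_round`.  Requesting a
    peptide absent from the table raises ``KeyError``.
    """

    def __init__(self, table: ActivityTable):
        self._by_peptide = {
            row.peptide: row for row in table.df.itertuples(index=False)
        }
        self._normalized = table.normalized

    @classmethod
    def from_csv(cls, path, normalized: bool = True) -> "TableOracle":
        return cls(ActivityTable.read_csv(path, normalized=normalized))

    def __call__(self, peptides, seed: int = 0, round_label: int = 0) -> ActivityTable:
        records = []
        for p in peptides:
            try:
                row = self._by_peptide[p]
            except KeyError:
                raise KeyError(f"peptide {p!r} has no measured record") from None
            rec = row._asdict()
            rec["round"] = round_label
            records.append(rec)
        return ActivityTable.from_records(records, normalized=self._normalized)


def run_round(
    state: RoundState,
    oracle: Oracle,
    policy: SelectionPolicy,
    config: ModelConfig,
    context: DesignContext,
    measure: bool = True,
) -> RoundState:
    """Train on the current table, score the space, select and measure.

    With ``policy.batch_size == 0`` (or ``measure=False``) the state advances
    with a fresh fit but no new data.  Oracle failures propagate after the
    pre-measurement state is fully formed, so a campaign can resume.
    """
    table = state.training
    y = table.df["relative_intensity"].to_numpy(dtype=float)
    X = context.rows_for(table.peptides)
    cv = train_cv(X, y, config)
    preds = predict_space(cv.model, context.X)

    ranked = sorted(
        range(len(context.peptides)),
        key=lambda i: (-preds[i], context.peptides[i]),
    )
    top100 = [context.peptides[i] for i in ranked[:100]]

    measured = frozenset(table.peptides)
    if measure and policy.batch_size > 0:
        batch = select_candidates(
            context.peptides, preds, context.X[context.descriptor_columns].to_numpy(),
            policy, exclude=measured,
        )
        batch_pred = np.array([preds[context.index[p]] for p in batch])
        new_data = oracle(batch, policy.seed, round_label=state.round_index + 1)
        table = table.concat(new_data)
    else:
        batch, batch_pred = [], np.empty(0)

    return RoundState(
        round_index=state.round_index + 1,
        training=table,
        cv=cv,
        candidates=batch,
        candidate_predictions=batch_pred,
        r_history=state.r_history + [cv.pooled_r],
        top100=top100,
    )


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Fan one campaign seed out to per-round seeds (documented derivation)."""
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def run_campaign(
    initial: ActivityTable,
    oracle: Oracle,
    n_rounds: int,
    policy: SelectionPolicy,
    config: ModelConfig,
    context: DesignContext,
    batch_sizes: Optional[Sequence[int]] = None,
    seed: Optional[int] = None,
    select_in_last_round: bool = False,
) -> CampaignHistory:
    """Run an iterative campaign of ``n_rounds`` train/select/measure cycles.

    ``batch_sizes`` overrides the policy's batch size per round (e.g. the
    +50/+40 accounting of a three-round campaign).  ``seed`` fans out to
    per-round model and selection seeds; when omitted the config/policy seeds
    are used as-is for every round.  By default no batch is measured after
    the final training round.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    seeds = _derive_seeds(seed, n_rounds) if seed is not None else None
    state = RoundState(
        round_index=0,
        training=initial,
        cv=None,
        candidates=[],
        candidate_predictions=np.empty(0),
        r_history=[],
    )
    rounds = []
    for r in range(n_rounds):
        cfg, pol = config, policy
        if seeds is not None:
            cfg = replace(config, seed=seeds[r])
            pol = replace(policy, seed=seeds[r])
        if batch_sizes is not None:
            pol = _resize_policy(pol, batch_sizes[r])
        last = r == n_rounds - 1
        state = run_round(
            state, oracle, pol, cfg, context,
            measure=(not last) or select_in_last_round,
        )
        rounds.append(state)
    return CampaignHistory(rounds=rounds)


def _resize_policy(policy: SelectionPolicy, batch_size: int) -> SelectionPolicy:
    """Rescale the strata proportionally to a new batch size."""
    if batch_size == policy.batch_size:
        return policy
    if batch_size == 0:
        return replace(policy, batch_size=0, n_top=0, n_cluster_reps=0, n_random=0)
    scale = batch_size / policy.batch_size
    n_top = round(policy.n_top * scale)
    n_reps = min(round(policy.n_cluster_reps * scale), policy.k_clusters)
    n_rand = batch_size - n_top - n_reps
    if n_rand < 0:
        n_top += n_rand
        n_rand = 0
    return replace(
        policy,
        batch_size=batch_size,
        n_top=n_top,
        n_cluster_reps=n_reps,
        n_random=n_rand,
    )
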