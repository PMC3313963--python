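"""Greedy performance training: weight training (WT) and matrix mutation (MaM).

Both stages are hill-climbers on the same objective: leave-one-out (LOO)
sensitivity at a fixed specificity of 90%.  A proposal perturbs either
one of the nine position weights or one substitution-matrix entry by
+/-1 (matrix entries symmetrically), the LOO score table is recomputed,
and the proposal is kept only if sensitivity strictly increased.  A
stage stops after a configurable run of consecutive rejections or a
hard proposal cap.

Weights and matrix entries start integer and move in +/-1 steps, so
every score is an exactly representable integer-valued float; the
incremental rescoring used here is therefore bit-identical to a full
recomputation, and a rejected proposal leaves the accepted state
untouched (candidate arrays are simply discarded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledNonamerSet
from .evaluation import (
    DEFAULT_TIER,
    TIER_SPECIFICITY,
    ScoreTable,
    calibrate_thresholds,
)
from .matrices import (
    AMINO_ACIDS,
    CORE_LENGTH,
    N_RESIDUES,
    PositionWeights,
    SubstitutionMatrix,
    encode_peptides,
    load_substitution_matrix,
)
from .scoring import score_against_cores

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Settings for the WT/MaM hill-climb and threshold calibration."""

    matrix_name: str = "BLOSUM62"
    sp_anchor: float = 0.90
    run_wt: bool = True
    run_mam: bool = True
    order: tuple[str, ...] = ("wt", "mam")
    patience: int = 1000  # consecutive rejections before a stage stops
    max_proposals: int = 20000  # hard cap per stage
    seed: int = 0
    haplotype: str = ""
    tier_specificity: dict = field(default_factory=lambda: dict(TIER_SPECIFICITY))


@dataclass
class TrainingObjective:
    """The training target: LOO sensitivity at a fixed specificity anchor."""

    sp_anchor: float = 0.90
    sn: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.sn <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")


def sn_at_fixed_sp(table: ScoreTable, sp_target: float) -> tuple[float, float]:
    """Sensitivity at the smallest cutoff achieving the target specificity.

    The threshold is chosen from the set of observed scores: the smallest
    value t such that the fraction of negatives scoring strictly above t
    is at most 1 - sp_target.  Returns (sensitivity, threshold).
    """
    if not 0.0 < sp_target <= 1.0:
        raise ValueError("sp_target must lie in (0, 1]")
    table.require_nonempty()
    pos = np.sort(table.positive_scores)
    neg = np.sort(table.negative_scores)
    candidates = np.unique(np.concatenate([pos, neg]))
    n_neg = neg.size
    fp_frac = (n_neg - np.searchsorted(neg, candidates, side="right")) / n_neg
    ok = fp_frac <= (1.0 - sp_target) + 1e-12
    threshold = float(candidates[int(np.argmax(ok))])  # fp_frac non-increasing
    sn = float((pos.size - np.searchsorted(pos, threshold, side="right")) / pos.size)
    return sn, threshold


def loo_score_table(
    positives, negatives, matrix: SubstitutionMatrix, weights=None
) -> ScoreTable:
    """Score positives by LOO against each other and negatives against all positives."""
    positives = [str(p) for p in positives]
    negatives = [str(n) for n in negatives]
    if len(positives) < 2:
        raise ValueError("leave-one-out scoring requires at least 2 positives")
    if not negatives:
        raise ValueError("leave-one-out scoring requires at least 1 negative")
    pos_codes = encode_peptides(positives, CORE_LENGTH)
    neg_codes = encode_peptides(negatives, CORE_LENGTH)
    p = score_against_cores(pos_codes, pos_codes, matrix, weights, leave_one_out=True)
    n = score_against_cores(neg_codes, pos_codes, matrix, weights)
    return ScoreTable(p, n, context="LOO",
                      positive_seqs=positives, negative_seqs=negatives)


# ---------------------------------------------------------------------------
# incremental-rescoring training state


def _pair_codes(q_codes: np.ndarray, c_codes: np.ndarray) -> np.ndarray:
    """Unordered residue-pair code per (query, core, position) entry."""
    a = q_codes[:, None, :].astype(np.int16)
    b = c_codes[None, :, :].astype(np.int16)
    return N_RESIDUES * np.minimum(a, b) + np.maximum(a, b)


class _PairIndex:
    """Flat entry indices of one per-position score tensor, grouped by pair code."""

    def __init__(self, codes: np.ndarray):
        flat = codes.ravel()
        self.order = np.argsort(flat, kind="stable").astype(np.int32)
        sorted_codes = flat[self.order]
        bins = np.arange(N_RESIDUES * N_RESIDUES + 1, dtype=np.int16)
        self.bounds = np.searchsorted(sorted_codes, bins)

    def entries(self, code: int) -> np.ndarray:
        return self.order[self.bounds[code] : self.bounds[code + 1]]


@dataclass
class _Proposal:
    kind: str  # "weight" | "matrix"
    payload: tuple
    raw_pp: np.ndarray
    raw_np: np.ndarray
    sn: float = 0.0
    threshold: float = 0.0


class TrainingState:
    """Mutable scoring state shared by the WT and MaM stages.

    Holds the encoded positive/negative nonamers, the current matrix and
    weights, the per-position score tensors and the raw (unclamped)
    weighted score matrices, and evaluates +/-1 proposals incrementally.
    """

    def __init__(
        self,
        positives,
        negatives,
        matrix: SubstitutionMatrix | None = None,
        weights: PositionWeights | None = None,
        sp_anchor: float = 0.90,
    ):
        self.pos_seqs = [str(p) for p in positives]
        self.neg_seqs = [str(n) for n in negatives]
        if len(self.pos_seqs) < 2:
            raise ValueError("training requires at least 2 positive cores")
        if not self.neg_seqs:
            raise ValueError("training requires at least 1 negative nonamer")
        self.pos_codes = encode_peptides(self.pos_seqs, CORE_LENGTH)
        self.neg_codes = encode_peptides(self.neg_seqs, CORE_LENGTH)
        self.matrix = (matrix or load_substitution_matrix()).copy()
        self.weights = (weights or PositionWeights()).copy()
        self.sp_anchor = sp_anchor

        # per-position pair-score tensors (int16 is ample for +/-1 drift)
        m = self.matrix.scores
        self.A_pp = m[self.pos_codes[:, None, :], self.pos_codes[None, :, :]].astype(np.int16)
        self.A_np = m[self.neg_codes[:, None, :], self.pos_codes[None, :, :]].astype(np.int16)
        self.raw_pp = self.A_pp @ self.weights.w
        self.raw_np = self.A_np @ self.weights.w
        self._pair_idx_pp: _PairIndex | None = None
        self._pair_idx_np: _PairIndex | None = None

    # -- scoring ------------------------------------------------------------

    @staticmethod
    def _loo_scores(raw_pp: np.ndarray) -> np.ndarray:
        clamped = np.maximum(raw_pp, 0.0)
        n = clamped.shape[0]
        return (clamped.sum(axis=1) - np.diagonal(clamped)) / (n - 1)

    @staticmethod
    def _neg_scores(raw_np: np.ndarray) -> np.ndarray:
        return np.maximum(raw_np, 0.0).mean(axis=1)

    def score_table(self, raw_pp=None, raw_np=None, context="LOO") -> ScoreTable:
        raw_pp = self.raw_pp if raw_pp is None else raw_pp
        raw_np = self.raw_np if raw_np is None else raw_np
        return ScoreTable(
            self._loo_scores(raw_pp), self._neg_scores(raw_np), context=context,
            positive_seqs=self.pos_seqs, negative_seqs=self.neg_seqs,
        )

    def objective(self) -> tuple[float, float]:
        return sn_at_fixed_sp(self.score_table(), self.sp_anchor)

    # -- proposals ----------------------------------------------------------

    def propose_weight(self, position: int, delta: int) -> _Proposal | None:
        """Candidate state with w[position] += delta; None if it would go negative."""
        if self.weights.w[position] + delta < 0:
            return None
        raw_pp = self.raw_pp + delta * self.A_pp[:, :, position]
        raw_np = self.raw_np + delta * self.A_np[:, :, position]
        return self._evaluated(_Proposal("weight", (position, delta), raw_pp, raw_np))

    def propose_matrix(self, a: int, b: int, delta: int) -> _Proposal:
        """Candidate state with matrix[a, b] (and [b, a]) += delta."""
        if self._pair_idx_pp is None:
            self._pair_idx_pp = _PairIndex(_pair_codes(self.pos_codes, self.pos_codes))
            self._pair_idx_np = _PairIndex(_pair_codes(self.neg_codes, self.pos_codes))
        code = N_RESIDUES * min(a, b) + max(a, b)
        raw_pp = self.raw_pp.copy()
        raw_np = self.raw_np.copy()
        for raw, idx in ((raw_pp, self._pair_idx_pp), (raw_np, self._pair_idx_np)):
            entries = idx.entries(code)
            if entries.size:
                cells = entries // CORE_LENGTH
                contrib = delta * self.weights.w[entries % CORE_LENGTH]
                np.add.at(raw.ravel(), cells, contrib)
        return self._evaluated(_Proposal("matrix", (a, b, delta), raw_pp, raw_np))

    def _evaluated(self, proposal: _Proposal) -> _Proposal:
        table = self.score_table(proposal.raw_pp, proposal.raw_np)
        proposal.sn, proposal.threshold = sn_at_fixed_sp(table, self.sp_anchor)
        return proposal

    def accept(self, proposal: _Proposal) -> None:
        if proposal.kind == "weight":
            position, delta = proposal.payload
            self.weights.w[position] += delta
        else:
            a, b, delta = proposal.payload
            self.matrix.scores[a, b] += delta
            if a != b:
                self.matrix.scores[b, a] += delta
            code = N_RESIDUES * min(a, b) + max(a, b)
            for A, idx in ((self.A_pp, self._pair_idx_pp), (self.A_np, self._pair_idx_np)):
                entries = idx.entries(code)
                if entries.size:
                    A.ravel()[entries] += delta
        self.raw_pp = proposal.raw_pp
        self.raw_np = proposal.raw_np


@dataclass
class StageRecord:
    """One proposal in a training stage trace."""

    stage: str
    step: int
    payload: tuple
    accepted: bool
    sn: float  # objective value after this step (unchanged if rejected)


def _greedy_stage(
    state: TrainingState,
    rng: np.random.Generator,
    config: TrainingConfig,
    stage: str,
) -> list[StageRecord]:
    sn, _ = state.objective()
    trace: list[StageRecord] = []
    rejections = 0
    for step in range(config.max_proposals):
        if rejections >= config.patience or sn >= 1.0:
            break
        if stage == "wt":
            position = int(rng.integers(CORE_LENGTH))
            delta = 1 if int(rng.integers(2)) == 0 else -1
            proposal = state.propose_weight(position, delta)
            payload = (position, delta)
        else:
            a = int(rng.integers(N_RESIDUES))
            b = int(rng.integers(N_RESIDUES))
            delta = 1 if int(rng.integers(2)) == 0 else -1
            proposal = state.propose_matrix(a, b, delta)
            payload = (a, b, delta)
        if proposal is not None and proposal.sn > sn:
            state.accept(proposal)
            sn = proposal.sn
            rejections = 0
            trace.append(StageRecord(stage, step, payload, True, sn))
        else:
            rejections += 1
            trace.append(StageRecord(stage, step, payload, False, sn))
    return trace


def weight_training(
    state: TrainingState, rng: np.random.Generator, config: TrainingConfig | None = None
) -> list[StageRecord]:
    """Greedy +/-1 perturbation of the nine position weights.

    Each proposal picks a uniformly random position and direction; it is
    kept only if LOO sensitivity at the specificity anchor strictly
    increases.  Weights never go below zero (a -1 proposal on a zero
    weight is auto-rejected).  Returns the full proposal trace.
    """
    return _greedy_stage(state, rng, config or TrainingConfig(), "wt")


def matrix_mutation(
    state: TrainingState, rng: np.random.Generator, config: TrainingConfig | None = None
) -> list[StageRecord]:
    """Greedy +/-1 perturbation of substitution-matrix entries.

    A proposal perturbs one residue-pair entry, applied jointly to (a, b)
    and (b, a) so the similarity function stays order-independent; the
    acceptance rule and stop rule match weight training.
    """
    return _greedy_stage(state, rng, config or TrainingConfig(), "mam")


# ---------------------------------------------------------------------------
# the trained model


@dataclass(eq=False)
class Model:
    """A trained predictor for one haplotype.

    Bundles the unique training cores, the (possibly mutated) substitution
    matrix, the trained position weights, and the specificity-calibrated
    tier cutoffs, plus provenance sufficient to reproduce the run.
    """

    cores: list[str]
    matrix: SubstitutionMatrix
    weights: PositionWeights
    thresholds: dict[str, float]
    haplotype: str = ""
    default_tier: str = DEFAULT_TIER
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self._encoded = None
        tiers = [t for t in ("high", "medium", "low") if t in self.thresholds]
        for hi, lo in zip(tiers, tiers[1:]):
            if self.thresholds[hi] < self.thresholds[lo]:
                raise ValueError("tier thresholds must be ordered high >= medium >= low")

    @property
    def encoded_cores(self) -> np.ndarray:
        if self._encoded is None:
            self._encoded = encode_peptides(self.cores, CORE_LENGTH)
        return self._encoded

    def threshold_for_tier(self, tier: str) -> float:
        if tier not in self.thresholds:
            raise ValueError(
                f"unknown tier {tier!r}; available: {', '.join(self.thresholds)}"
            )
        return self.thresholds[tier]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Model)
            and self.cores == other.cores
            and self.matrix == other.matrix
            and self.weights == other.weights
            and self.thresholds == other.thresholds
            and self.haplotype == other.haplotype
            and self.default_tier == other.default_tier
            and self.provenance == other.provenance
        )

    # -- text serialization (lossless round trip) ---------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# epicore model v1\n")
            fh.write("[meta]\n")
            fh.write(f"haplotype = {self.haplotype}\n")
            fh.write(f"default_tier = {self.default_tier}\n")
            fh.write(f"matrix_name = {self.matrix.name}\n")
            fh.write("[matrix]\n")
            fh.write(self.matrix.to_text())
            fh.write("[weights]\n")
            fh.write(" ".join(repr(float(w)) for w in self.weights.w) + "\n")
            fh.write("[thresholds]\n")
            for tier, t in self.thresholds.items():
                fh.write(f"{tier} = {float(t)!r}\n")
            fh.write("[cores]\n")
            for core in self.cores:
                fh.write(core + "\n")
            fh.write("[provenance]\n")
            for key, value in self.provenance.items():
                fh.write(f"{key} = {json.dumps(value)}\n")

    @classmethod
    def load(cls, path) -> "Model":
        sections: dict[str, list[str]] = {}
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if line.startswith("[") and line.endswith("]"):
                    current = line[1:-1]
                    sections[current] = []
                elif current is not None:
                    sections[current].append(line)
        if "matrix" not in sections or "cores" not in sections:
            raise ValueError(f"{path} is not a valid model file")
        meta = dict(ln.split(" = ", 1) for ln in sections.get("meta", []))
        matrix = SubstitutionMatrix.from_text(
            "\n".join(sections["matrix"]), meta.get("matrix_name", "custom")
        )
        weights = PositionWeights(
            np.array([float(x) for x in sections["weights"][0].split()])
        )
        thresholds = {
            k: float(v) for k, v in (ln.split(" = ", 1) for ln in sections["thresholds"])
        }
        provenance = {
            k: json.loads(v)
            for k, v in (ln.split(" = ", 1) for ln in sections.get("provenance", []))
        }
        return cls(
            cores=sections["cores"],
            matrix=matrix,
            weights=weights,
            thresholds=thresholds,
            haplotype=meta.get("haplotype", ""),
            default_tier=meta.get("default_tier", DEFAULT_TIER),
            provenance=provenance,
        )


def train_model(positives, negatives, config: TrainingConfig | None = None) -> Model:
    """Train a predictor: optional WT and MaM stages, then tier calibration.

    ``positives`` are the unique 9-mer cores; ``negatives`` the unique
    negative windows (any overlap with positives is removed).  With both
    stages disabled this yields the plain unit-weight starting-matrix
    baseline.  The result is fully determined by (data, config).
    """
    config = config or TrainingConfig()
    data = LabeledNonamerSet(list(map(str, positives)), list(map(str, negatives)))
    state = TrainingState(
        data.positives,
        data.negatives,
        matrix=load_substitution_matrix(config.matrix_name),
        sp_anchor=config.sp_anchor,
    )
    rng = np.random.default_rng(config.seed)
    sn0, _ = state.objective()
    sn_trace = [sn0]
    stage_steps: dict[str, int] = {}
    enabled = {"wt": config.run_wt, "mam": config.run_mam}
    for stage in config.order:
        if not enabled.get(stage, False):
            continue
        runner = weight_training if stage == "wt" else matrix_mutation
        trace = runner(state, rng, config)
        stage_steps[stage] = len(trace)
        sn_trace.extend(rec.sn for rec in trace if rec.accepted)

    table = state.score_table()
    thresholds = calibrate_thresholds(table, config.tier_specificity)
    matrix = state.matrix.copy()
    if stage_steps.get("mam") and not np.array_equal(
        matrix.scores, load_substitution_matrix(config.matrix_name).scores
    ):
        matrix.name = f"{config.matrix_name}+MaM"
    final_sn, _ = state.objective()
    logger.info(
        "training finished: Sn at Sp %.0f%% went %.4f -> %.4f",
        100 * config.sp_anchor, sn0, final_sn,
    )
    return Model(
        cores=list(data.positives),
        matrix=matrix,
        weights=state.weights.copy(),
        thresholds=thresholds,
        haplotype=config.haplotype,
        provenance={
            "seed": config.seed,
            "matrix_name": config.matrix_name,
            "sp_anchor": config.sp_anchor,
            "order": [s for s in config.order if enabled.get(s, False)],
            "patience": config.patience,
            "max_proposals": config.max_proposals,
            "stage_proposals": stage_steps,
            "sn_trace": [float(s) for s in sn_trace],
            "n_positives": len(data.positives),
            "n_negatives": len(data.negatives),
        },
    )
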