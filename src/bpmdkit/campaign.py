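"""Replica orchestration, pose ranking and evaluation statistics.

A campaign runs ``n_replicas`` independent biased simulations per candidate
pose (replica i is seeded with ``master_seed + i``), scores each replica,
and ranks poses by the replica-mean CompScore (ascending: most negative =
most stable). Ties are broken by mean PoseScore, then by pose id, so the
ranking is deterministic.

The statistics helpers mirror the benchmark-style evaluation: top-pose
classification against the native geometry at 2/3 Å thresholds, success
rates over systems, Pearson correlation between pose RMSD and CompScore,
and a paired two-sided Wilcoxon signed-rank test (exact null by enumeration
up to n = 15, tie-corrected normal approximation above).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata, norm

from .anchors_cv import AlignedRmsdCV
from .config import ProtocolConfig
from .metadynamics import Engine, MetadParams
from .scoring import PoseScores, ScoreSeries, score_replica
from .system_io import PoseSet, pose_complex, write_score_table

__all__ = [
    "ReplicaResult",
    "CampaignResult",
    "run_campaign",
    "classify_top_pose",
    "success_rate",
    "pearson_rmsd_score",
    "wilcoxon_paired",
]

SCORE_FIELDS = ("pose_score", "pers_score", "contact_score", "comp_score")


@dataclass
class ReplicaResult:
    pose_id: object
    replica_index: int
    seed: int
    scores: PoseScores
    series: ScoreSeries


@dataclass
class CampaignResult:
    summary: pd.DataFrame          # one row per pose: mean/sd of each score
    replicas: list[ReplicaResult]
    ranking: list                  # pose_ids, most stable first
    failures: dict = field(default_factory=dict)  # pose_id -> [(replica, error)]
    top_pose_rmsd_to_native: Optional[float] = None

    def mean_comp_score(self, pose_id) -> float:
        row = self.summary[self.summary["pose_id"] == pose_id]
        return float(row["comp_score_mean"].iloc[0])

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False, float_format="%.6f")

    def replica_rows(self) -> list[dict]:
        return [{
            "pose_id": r.pose_id, "replica": r.replica_index,
            "PoseScore": r.scores.pose_score, "PersScore": r.scores.pers_score,
            "ContactScore": r.scores.contact_score, "CompScore": r.scores.comp_score,
        } for r in self.replicas]


def run_campaign(pose_set: PoseSet, config: ProtocolConfig, engine: Engine,
                 out_dir: Optional[str | Path] = None) -> CampaignResult:
    """Run and score n_replicas biased simulations for every pose.

    A replica failure is recorded and the pose stays in the ranking unless
    every one of its replicas failed. With ``out_dir`` set, the per-replica
    and summary CSVs (and a JSON ranking summary) are written there.
    """
    params = MetadParams.from_config(config)
    replicas: list[ReplicaResult] = []
    failures: dict = {}
    rows = []
    for pose_id in pose_set.pose_ids:
        complex = pose_complex(pose_set, pose_id)
        cv = AlignedRmsdCV.from_complex(complex, anchor_cutoff=config.anchor_cutoff)
        ok = []
        for i in range(config.n_replicas):
            seed = config.seed + i
            try:
                traj = engine.run(pose_id, complex, cv, params, seed)
                scores, series = score_replica(traj, complex, cv, config)
            except Exception as exc:
                failures.setdefault(pose_id, []).append((i, str(exc)))
                continue
            rep = ReplicaResult(pose_id=pose_id, replica_index=i, seed=seed,
                                scores=scores, series=series)
            replicas.append(rep)
            ok.append(scores)
        if ok:
            row = {"pose_id": pose_id, "n_replicas": len(ok)}
            for f in SCORE_FIELDS:
                vals = np.array([getattr(s, f) for s in ok])
                row[f"{f}_mean"] = vals.mean()
                row[f"{f}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row["pers_defined"] = all(s.pers_defined for s in ok)
            rows.append(row)
    if not rows:
        raise RuntimeError("all replicas of every pose failed")
    summary = pd.DataFrame(rows)
    order = sorted(range(len(rows)),
                   key=lambda i: (rows[i]["comp_score_mean"],
                                  rows[i]["pose_score_mean"],
                                  str(rows[i]["pose_id"])))
    ranking = [rows[i]["pose_id"] for i in order]
    result = CampaignResult(summary=summary, replicas=replicas,
                            ranking=ranking, failures=failures)
    if pose_set.native_ligand is not None and ranking:
        result.top_pose_rmsd_to_native = _pose_rmsd_to_native(
            pose_set, ranking[0])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_score_table(result.replica_rows(), out / "replica_scores.csv")
        result.to_csv(out / "campaign_summary.csv")
        (out / "ranking.json").write_text(json.dumps({
            "ranking": [str(p) for p in ranking],
            "top_pose_rmsd_to_native": result.top_pose_rmsd_to_native,
        }, indent=2))
    return result


def _pose_rmsd_to_native(pose_set: PoseSet, pose_id) -> float:
    """Heavy-atom RMSD of a pose's starting geometry to the native ligand.

    Both geometries live in the same receptor frame, so the anchor
    superposition is the identity and no ligand fitting is applied.
    """
    if pose_set.native_ligand is None:
        raise ValueError("pose set has no native ligand")
    heavy = np.array([a.is_heavy for a in pose_set.ligand_atoms])
    d = pose_set.pose_coords(pose_id)[heavy] - np.asarray(pose_set.native_ligand)[heavy]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def classify_top_pose(result: CampaignResult, pose_set: PoseSet,
                      thresholds: Sequence[float] = (2.0, 3.0)) -> dict[float, bool]:
    """Success per RMSD threshold for the top-ranked pose vs the native."""
    rmsd = _pose_rmsd_to_native(pose_set, result.ranking[0])
    result.top_pose_rmsd_to_native = rmsd
    return {float(t): bool(rmsd <= t) for t in thresholds}


def success_rate(classifications: Sequence[dict[float, bool]]) -> dict[float, float]:
    """Fraction of systems classified successful, per threshold."""
    if not classifications:
        raise ValueError("need at least one classification")
    thresholds = classifications[0].keys()
    return {t: sum(c[t] for c in classifications) / len(classifications)
            for t in thresholds}


def pearson_rmsd_score(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson r between pose RMSDs and their mean CompScores."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(pearsonr(x, y).statistic)


def wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; ties get average ranks. The statistic is
    min(W+, W−). The p-value uses the exact null distribution (enumeration
    of all sign assignments, valid with ties) for n <= 15 and the
    tie-corrected normal approximation above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    s_total = float(ranks.sum())
    stat = min(w_plus, s_total - w_plus)

    if n <= 15:
        lo, hi = min(w_plus, s_total - w_plus), max(w_plus, s_total - w_plus)
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            t = float(np.dot(signs, ranks))
            if t <= lo + 1e-9 or t >= hi - 1e-9:
                count += 1
        p = count / 2.0 ** n
    else:
        mean = s_total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return stat, float(min(p, 1.0))
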