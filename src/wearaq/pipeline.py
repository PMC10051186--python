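"""Campaign-level orchestration: simulate → curate → train → annotate →
post-process → summarize, with a grouped (by-participant) train/test split.

This is the glue used by the worked examples and the reproduction script;
each step is a plain call into the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balancing import balance
from .context import ModelConfig, evaluate, extract_views, predict, train
from .core import FusedTable
from .curation import CurationConfig, curate
from .postprocess import PostprocessConfig, postprocess
from .simulate import ArtifactModel, EmissionModel, generate_campaign
from .summary import pooled_exposure_summary


@dataclass
class CampaignResult:
    """Everything the end-to-end run computes."""

    tables: dict                    # participant -> labelled FusedTable
    truth_labels: dict              # participant -> truth label Series
    removal_reports: dict
    model: object
    raw_eval: dict                  # pooled over held-out participants
    post_eval: dict
    per_participant: dict           # pid -> {"raw": acc, "post": acc}
    summary: dict                   # exposure summary on final labels
    test_participants: list

    @property
    def removal_fraction(self) -> float:
        tot_removed = sum(r.total_removed for r in self.removal_reports.values())
        tot_input = sum(r.input_values for r in self.removal_reports.values())
        return tot_removed / tot_input if tot_input else 0.0


def prepare_participants(bundles, curation_config=None):
    """Curate every bundle and attach ground-truth labels."""
    tables, truths, reports = {}, {}, {}
    for bundle in bundles:
        table, report = curate(bundle, curation_config or CurationConfig())
        truth = bundle.annotations.label_minutes(table.frame.index)
        tables[bundle.participant_id] = table.with_labels(truth)
        truths[bundle.participant_id] = truth
        reports[bundle.participant_id] = report
    return tables, truths, reports


def run_campaign(n_participants: int = 10,
                 duration_days: float = 7.0,
                 n_train: int | None = None,
                 seed: int = 0,
                 emission: EmissionModel | None = None,
                 artifacts: ArtifactModel | None = None,
                 model_config: ModelConfig | None = None,
                 curation_config: CurationConfig | None = None,
                 postprocess_config: PostprocessConfig | None = None,
                 shuffle_labels: bool = False) -> CampaignResult:
    """Run the whole pipeline on a synthetic campaign.

    The train/test split is grouped by participant (the first ``n_train``
    participants train the model; default: all but three).  With
    ``shuffle_labels`` the training labels are permuted — a chance-level
    control.
    """
    if n_train is None:
        n_train = max(1, n_participants - 3)
    if not 1 <= n_train < n_participants:
        raise ValueError("need at least one training and one test participant")
    model_config = model_config or ModelConfig()
    bundles, truths_raw = generate_campaign(
        n_participants=n_participants, duration_days=duration_days,
        emission=emission, artifacts=artifacts, seed=seed)
    tables, truths, reports = prepare_participants(bundles, curation_config)
    pids = [b.participant_id for b in bundles]
    train_ids, test_ids = pids[:n_train], pids[n_train:]

    feats, labs = [], []
    for pid in train_ids:
        table = tables[pid]
        f = extract_views(table, model_config.window_minutes)
        ok = table.labels.notna().to_numpy()
        feats.append(f[ok])
        labs.append(table.labels[ok])
    X = pd.concat(feats, ignore_index=True)
    y = pd.concat(labs, ignore_index=True)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1)
        y = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    balanced = balance(X, y, seed=seed)
    model = train(balanced.features, balanced.labels, model_config, seed=seed)

    per_participant = {}
    raw_pred, post_pred, truth_all = [], [], []
    final_labels = {}
    for pid in test_ids:
        table = tables[pid]
        pred = predict(model, table)
        final, _ = postprocess(pred["label"], table,
                               postprocess_config or PostprocessConfig())
        truth = truths[pid]
        per_participant[pid] = {
            "raw": evaluate(pred["label"], truth)["accuracy"],
            "post": evaluate(final, truth)["accuracy"],
        }
        raw_pred.append(pred["label"])
        post_pred.append(final)
        truth_all.append(truth)
        final_labels[pid] = final
    truth_cat = pd.concat(truth_all)
    raw_eval = evaluate(pd.concat(raw_pred), truth_cat)
    post_eval = evaluate(pd.concat(post_pred), truth_cat)
    summary = pooled_exposure_summary({p: tables[p] for p in test_ids},
                                      labels=final_labels)
    return CampaignResult(tables=tables, truth_labels=truths,
                          removal_reports=reports, model=model,
                          raw_eval=raw_eval, post_eval=post_eval,
                          per_participant=per_participant, summary=summary,
                          test_participants=test_ids)
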