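"""Parameter-recovery metrics against simulation truth.

Homoeologous-set recovery is scored up to relabelling: predicted
region indices are matched to truth sets by a Hungarian assignment on
the contingency table, and slot phasing is scored with the adjusted
Rand index over (set, slot) partitions — slot labels a/b/c are
arbitrary by design.
"""

from __future__ import annotations

import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .agb import ModelGenome
from .simulate import SimulationTruth

__all__ = [
    "predicted_labels", "truth_labels", "set_accuracy", "slot_ari",
    "precision_recall", "agb_recovery",
]


def predicted_labels(model: ModelGenome) -> pd.DataFrame:
    """Per ingroup gene: predicted (set_index, slot) from the model genome."""
    rows = []
    for mg, src in model.provenance.items():
        meta = model.chrom_meta[model.annotation.chrom_of(mg)]
        rows.append(dict(gene_id=src, set_index=meta["set_index"], slot=meta["slot"]))
    return pd.DataFrame(rows).set_index("gene_id")


def truth_labels(genes, truth: SimulationTruth) -> pd.DataFrame:
    """Per gene: truth homoeologous set and subgenome."""
    rows = []
    for g in genes:
        anc = truth.ancestral_gene_of.get(g)
        if anc is None or anc not in truth.homoeologous_set_of:
            continue
        rows.append(dict(gene_id=g, set_index=truth.homoeologous_set_of[anc],
                         subgenome=truth.subgenome_of.get(g)))
    return pd.DataFrame(rows).set_index("gene_id")


def set_accuracy(pred: pd.Series, truth: pd.Series) -> float:
    """Fraction of genes whose predicted set matches truth under the
    best bijective set relabelling (Hungarian on the contingency table)."""
    joined = pd.concat([pred.rename("pred"), truth.rename("truth")], axis=1).dropna()
    if joined.empty:
        return 0.0
    table = pd.crosstab(joined["pred"], joined["truth"])
    rows, cols = linear_sum_assignment(-table.to_numpy())
    matched = table.to_numpy()[rows, cols].sum()
    return float(matched / len(joined))


def slot_ari(pred: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Adjusted Rand index between (set, slot) and (truth set, subgenome)."""
    joined = pred.join(truth, how="inner", lsuffix="_p", rsuffix="_t").dropna()
    if joined.empty:
        return 0.0
    a = [f"{s}|{sl}" for s, sl in zip(joined["set_index_p"], joined["slot"])]
    b = [f"{s}|{sl}" for s, sl in zip(joined["set_index_t"], joined["subgenome"])]
    return float(adjusted_rand_score(a, b))


def precision_recall(called: set, truth: set):
    tp = len(called & truth)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall


def agb_recovery(model: ModelGenome, truth: SimulationTruth):
    """(set accuracy, slot ARI, coverage) of a model genome vs truth."""
    pred = predicted_labels(model)
    tr = truth_labels(pred.index, truth)
    acc = set_accuracy(pred["set_index"], tr["set_index"])
    ari = slot_ari(pred, tr)
    return acc, ari, len(pred)
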