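"""Scoring pipeline output against synthetic ground truth.

Only meaningful for synthetic cohorts: maps merged compounds back to the
library they were rendered from, and scores how many planted discriminatory
VOCs the selection recovered, with the right direction of change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import CompoundTable
from .synthetic import CompoundLibrary, GroundTruth


def match_compounds_to_library(
    table: CompoundTable,
    library: CompoundLibrary,
    rt_tolerance: float = 0.15,
    min_correlation: float = 0.7,
) -> dict[str, str]:
    """Map merged compound ids to library compound ids.

    Each merged compound is assigned to the library compound with the
    highest spectral correlation among those within ``rt_tolerance`` of its
    consensus retention time; unmatched compounds are omitted.
    """
    mapping: dict[str, str] = {}
    lib_rt = library.true_rt
    for k, cid in enumerate(table.values.columns):
        rt = table.consensus_rt.iloc[k]
        cand = np.flatnonzero(np.abs(lib_rt - rt) <= rt_tolerance)
        best, best_corr = None, min_correlation
        spec = table.consensus_spectra[k]
        for j in cand:
            lib_spec = library.spectra[j]
            if spec.std() == 0 or lib_spec.std() == 0:
                continue
            corr = float(np.corrcoef(spec, lib_spec)[0, 1])
            if corr >= best_corr:
                best, best_corr = library.compound_ids[j], corr
        if best is not None:
            mapping[cid] = best
    return mapping


def estimated_signs(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    positive_class: str = "asthma",
    negative_class: str = "transient_wheeze",
) -> pd.Series:
    """Sign of each compound's class-mean difference (positive - negative)."""
    cls = meta.set_index("sample_id").loc[table.index, "class"]
    mu_pos = table[cls == positive_class].mean(axis=0)
    mu_neg = table[cls == negative_class].mean(axis=0)
    return np.sign(mu_pos - mu_neg).astype(int)


def recovery_score(
    selected: list[str],
    truth: GroundTruth,
    mapping: dict[str, str] | None = None,
    signs: pd.Series | None = None,
) -> dict:
    """Recall of planted discriminatory VOCs and sign agreement.

    ``mapping`` translates selected (merged) compound ids to library ids;
    omit it when the table columns already are library ids.  ``signs`` are
    estimated asthma-vs-transient directions indexed like ``selected``;
    sign agreement is scored only on planted compounds with a nonzero
    planted direction.
    """
    if mapping is None:
        mapping = {cid: cid for cid in selected}
    recovered = {mapping[c] for c in selected if c in mapping}
    planted = set(truth.discriminatory)
    hits = recovered & planted
    recall = len(hits) / len(planted) if planted else float("nan")
    sign_checked = sign_correct = 0
    if signs is not None:
        lib_by_sel = {c: mapping.get(c) for c in selected}
        for sel_id, lib_id in lib_by_sel.items():
            if lib_id in planted and truth.signs.get(lib_id, 0) != 0:
                sign_checked += 1
                if int(signs.get(sel_id, 0)) == truth.signs[lib_id]:
                    sign_correct += 1
    return {
        "n_planted": len(planted),
        "n_selected": len(selected),
        "n_recovered": len(hits),
        "recall": recall,
        "sign_checked": sign_checked,
        "sign_correct": sign_correct,
        "sign_agreement": (sign_correct / sign_checked) if sign_checked else None,
    }
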