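"""Associate perturbation signatures with cell-viability phenotypes.

Signatures and viability records are joined on cell line and perturbagen
id; compound records additionally require the treatment dose and the
signature dose to agree on a log scale (``|log10 Cdose - log10 Ldose| <=
0.2``).  Records from different experimental batches that pass the match
are averaged into a single viability target per signature instance.
Matched datasets can then be subset by perturbation time and, for compound
screens, extended with log10(dose) as an explicit predictor (the S2
variant; S1 uses genes only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import META_COLS

logger = logging.getLogger(__name__)

DOSE_MATCH_THRESHOLD = 0.2
DOSE_FEATURE = "log10_dose"


@dataclass
class MatchedDataset:
    """Aligned signatures and viability targets.

    ``X`` holds the predictor matrix (genes, plus :data:`DOSE_FEATURE`
    when the concentration factor is included), ``y`` the viability target
    aligned row-for-row, and ``meta`` the instance metadata with per-row
    match multiplicities.
    """

    X: pd.DataFrame
    y: pd.Series
    meta: pd.DataFrame
    s2: bool = False
    time_h: float | None = None
    extra_cols: tuple = ()
    n_unmatched: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> list:
        return [c for c in self.X.columns if c not in self.extra_cols]

    def __len__(self) -> int:
        return len(self.y)

    def write(self, matrix_path, target_path) -> None:
        self.X.to_csv(matrix_path, index=False)
        pd.DataFrame({"instance_id": self.meta["instance_id"], "viability": self.y}).to_csv(
            target_path, index=False
        )


def _gene_columns(sig: pd.DataFrame) -> list:
    return [c for c in sig.columns if c not in META_COLS]


def merge_phases(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Row-concatenate two signature phases on their shared gene universe.

    Duplicate instance_ids keep the first occurrence; a non-identical gene
    universe is intersected with a warning, an empty intersection is an
    error.
    """
    if len(b) == 0:
        return a.copy()
    if len(a) == 0:
        return b.copy()
    ga, gb = _gene_columns(a), _gene_columns(b)
    shared = [g for g in ga if g in set(gb)]
    if not shared:
        raise ValueError("no genes shared between the two phases")
    if len(shared) != len(ga) or len(shared) != len(gb):
        logger.warning(
            "gene universes differ: intersecting to %d shared genes (%d vs %d)",
            len(shared), len(ga), len(gb),
        )
    merged = pd.concat([a[META_COLS + shared], b[META_COLS + shared]], ignore_index=True)
    dup = merged["instance_id"].duplicated()
    for iid in merged.loc[dup, "instance_id"]:
        logger.warning("duplicate instance_id %s dropped (keeping first occurrence)", iid)
    return merged.loc[~dup].reset_index(drop=True)


def dose_match(cdose: float, ldose: float, threshold: float = DOSE_MATCH_THRESHOLD) -> bool:
    """True when two µM doses agree within ``threshold`` on the log10 scale."""
    if cdose <= 0 or ldose <= 0:
        raise ValueError("doses must be positive")
    return abs(np.log10(cdose) - np.log10(ldose)) <= threshold


def _norm_key(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.lower()


def match_viability(
    signatures: pd.DataFrame,
    phenotypes: pd.DataFrame,
    by_dose: bool = True,
    threshold: float = DOSE_MATCH_THRESHOLD,
) -> MatchedDataset:
    """Match each signature instance to viability records and average them.

    Candidate records share the cell line and perturbagen id (string
    equality after whitespace/case normalisation) and, for compound data
    (``by_dose=True``), pass :func:`dose_match`.  The target is the
    arithmetic mean of the viability over all passing records; instances
    with no passing record are dropped and counted.
    """
    genes = _gene_columns(signatures)
    phen = phenotypes.copy()
    phen["_cl"] = _norm_key(phen["cell_line"])
    phen["_pid"] = _norm_key(phen["pert_id"])
    groups = {k: g for k, g in phen.groupby(["_cl", "_pid"], sort=False)}

    targets, multiplicity, keep = [], [], []
    for i, row in enumerate(signatures.itertuples(index=False)):
        key = (str(row.cell_line).strip().lower(), str(row.pert_id).strip().lower())
        g = groups.get(key)
        if g is None:
            continue
        if by_dose:
            ld = row.dose_um
            if pd.isna(ld) or ld <= 0:
                raise ValueError(f"instance {row.instance_id} lacks a positive dose")
            cd = g["dose_um"].to_numpy(float)
            ok = np.abs(np.log10(cd) - np.log10(float(ld))) <= threshold
            vals = g.loc[ok, "viability"].to_numpy(float)
        else:
            vals = g["viability"].to_numpy(float)
        if vals.size == 0:
            continue
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite viability in matched records")
        keep.append(i)
        targets.append(float(vals.mean()))
        multiplicity.append(int(vals.size))

    n_unmatched = len(signatures) - len(keep)
    if n_unmatched:
        logger.warning("%d signature instances had no matching viability record", n_unmatched)
    if not keep:
        logger.warning("no instance matched any viability record: empty dataset")
    meta = signatures.iloc[keep][META_COLS].reset_index(drop=True)
    meta["n_matched_records"] = multiplicity
    X = signatures.iloc[keep][genes].reset_index(drop=True)
    y = pd.Series(targets, name="viability")
    return MatchedDataset(
        X=X, y=y, meta=meta, s2=False, n_unmatched=n_unmatched,
        provenance={"by_dose": by_dose, "threshold": threshold, "n_input": len(signatures)},
    )


def subset_by_time(ds: MatchedDataset, hours: float) -> MatchedDataset:
    """Keep only rows whose perturbation time equals ``hours``."""
    mask = (ds.meta["time_h"] == hours).to_numpy()
    if not mask.any():
        logger.warning("no instances at time %s h: empty subset", hours)
    return MatchedDataset(
        X=ds.X.loc[mask].reset_index(drop=True),
        y=ds.y.loc[mask].reset_index(drop=True),
        meta=ds.meta.loc[mask].reset_index(drop=True),
        s2=ds.s2,
        time_h=float(hours),
        extra_cols=ds.extra_cols,
        n_unmatched=ds.n_unmatched,
        provenance={**ds.provenance, "time_h": float(hours)},
    )


def with_concentration_feature(ds: MatchedDataset) -> MatchedDataset:
    """Append log10(dose) as an extra predictor, flagging the dataset S2."""
    dose = ds.meta["dose_um"].to_numpy(float)
    if np.any(~np.isfinite(dose)) or np.any(dose <= 0):
        raise ValueError("concentration feature requires a positive dose on every row")
    X = ds.X.copy()
    X[DOSE_FEATURE] = np.log10(dose)
    return MatchedDataset(
        X=X, y=ds.y.copy(), meta=ds.meta.copy(), s2=True, time_h=ds.time_h,
        extra_cols=tuple(ds.extra_cols) + (DOSE_FEATURE,),
        n_unmatched=ds.n_unmatched,
        provenance={**ds.provenance, "s2": True},
    )
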