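"""Match probe-level copy-number and expression tracks at the gene level.

For each expression probe carrying a gene symbol, the copy-number probe at
the nearest genomic location on the same chromosome is paired with it
(equidistant ties go to the lower coordinate).  Copy-number values,
expression values, and genomic positions are then averaged per gene symbol,
yielding one matched copy-number row and one expression row per gene.
Averaging is done on the log2 scale, consistent with the log-linear cis
model downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import GeneTable, GenomicMatrix

logger = logging.getLogger("ipac.genematch")


def _nearest_probe_rows(expr_pos: np.ndarray, cn_pos: np.ndarray) -> np.ndarray:
    """Index into cn_pos of the nearest position for each expression probe.

    cn_pos must be sorted ascending; ties (exactly equidistant neighbours)
    resolve to the lower coordinate.
    """
    right = np.searchsorted(cn_pos, expr_pos, side="left")
    right = np.clip(right, 0, len(cn_pos) - 1)
    left = np.clip(right - 1, 0, len(cn_pos) - 1)
    d_left = np.abs(expr_pos - cn_pos[left])
    d_right = np.abs(cn_pos[right] - expr_pos)
    return np.where(d_left <= d_right, left, right)


def match_probes(expr: GenomicMatrix, cn: GenomicMatrix) -> GeneTable:
    """Build gene-level matched matrices from probe-level tracks.

    ``cn`` is expected to hold PCF values (the pipeline matches after
    segmentation), but any probe-level copy-number matrix works.  Expression
    probes without a gene symbol are ignored; probes on a chromosome with no
    copy-number coverage drop their gene (with a warning) unless the symbol
    has probes on a covered chromosome.
    """
    expr.check_aligned(cn)
    if "gene_symbol" not in expr.annotations.columns:
        raise ValueError("expression matrix carries no gene symbols")

    eann = expr.annotations
    has_symbol = eann["gene_symbol"].notna() & (eann["gene_symbol"].astype(str) != "")
    n_dropped = int((~has_symbol).sum())
    if n_dropped:
        logger.info("ignoring %d expression probes without gene symbol", n_dropped)

    evalues = expr.values.to_numpy()
    cvalues = cn.values.to_numpy()
    cann = cn.annotations

    # per-chromosome sorted CN probe positions
    cn_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idx in cann.groupby("chromosome", sort=False).groups.items():
        rows = np.asarray([cn.values.index.get_loc(i) for i in idx])
        pos = cann.loc[idx, "position"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        cn_by_chrom[str(chrom)] = (pos[order], rows[order])

    probe_rows = []   # (symbol, chromosome, position, expr_row_idx, cn_row_idx)
    missing_chrom: set[str] = set()
    sub = eann[has_symbol]
    for chrom, idx in sub.groupby("chromosome", sort=False).groups.items():
        chrom = str(chrom)
        erows = np.asarray([expr.values.index.get_loc(i) for i in idx])
        epos = sub.loc[idx, "position"].to_numpy()
        symbols = sub.loc[idx, "gene_symbol"].astype(str).to_numpy()
        if chrom not in cn_by_chrom:
            missing_chrom.update(symbols)
            continue
        cpos, crows = cn_by_chrom[chrom]
        nearest = _nearest_probe_rows(epos.astype(float), cpos.astype(float))
        for sym, p, er, k in zip(symbols, epos, erows, nearest):
            probe_rows.append((sym, chrom, float(p), er, crows[k]))

    if missing_chrom:
        matched_syms = {r[0] for r in probe_rows}
        lost = sorted(missing_chrom - matched_syms)
        if lost:
            logger.warning("dropping %d genes on chromosomes without "
                           "copy-number probes (e.g. %s)", len(lost), lost[:5])

    if not probe_rows:
        raise ValueError("no expression probe could be matched to a copy-number probe")

    df = pd.DataFrame(probe_rows, columns=["gene_symbol", "chromosome",
                                           "position", "erow", "crow"])
    # a symbol annotated on several chromosomes keeps its majority chromosome
    # (ties to the lexicographically first), restricted to probes on it
    chrom_of = (df.groupby(["gene_symbol", "chromosome"]).size()
                  .reset_index(name="n")
                  .sort_values(["gene_symbol", "n", "chromosome"],
                               ascending=[True, False, True], kind="mergesort")
                  .drop_duplicates("gene_symbol"))
    multi = (df.groupby("gene_symbol")["chromosome"].nunique() > 1)
    if multi.any():
        logger.warning("%d gene symbols span multiple chromosomes; keeping "
                       "majority chromosome", int(multi.sum()))
    df = df.merge(chrom_of[["gene_symbol", "chromosome"]],
                  on=["gene_symbol", "chromosome"], how="inner")

    genes = sorted(df["gene_symbol"].unique())
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_samples = expr.n_samples
    cn_sum = np.zeros((len(genes), n_samples))
    cn_cnt = np.zeros((len(genes), n_samples))
    ex_sum = np.zeros((len(genes), n_samples))
    ex_cnt = np.zeros((len(genes), n_samples))
    pos_sum = np.zeros(len(genes))
    pos_cnt = np.zeros(len(genes))
    chrom_out = [""] * len(genes)
    for sym, chrom, p, er, cr in df.itertuples(index=False):
        g = gene_idx[sym]
        ev = evalues[er]
        cv = cvalues[cr]
        em = np.isfinite(ev)
        cm = np.isfinite(cv)
        ex_sum[g, em] += ev[em]
        ex_cnt[g, em] += 1
        cn_sum[g, cm] += cv[cm]
        cn_cnt[g, cm] += 1
        pos_sum[g] += p
        pos_cnt[g] += 1
        chrom_out[g] = chrom

    with np.errstate(invalid="ignore"):
        expr_mat = np.where(ex_cnt > 0, ex_sum / np.maximum(ex_cnt, 1), np.nan)
        cn_mat = np.where(cn_cnt > 0, cn_sum / np.maximum(cn_cnt, 1), np.nan)

    index = pd.Index(genes, name="gene_symbol")
    ann = pd.DataFrame({"chromosome": chrom_out,
                        "position": pos_sum / pos_cnt}, index=index)
    return GeneTable(
        cn=pd.DataFrame(cn_mat, index=index, columns=expr.samples),
        expr=pd.DataFrame(expr_mat, index=index, columns=expr.samples),
        annotations=ann)
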