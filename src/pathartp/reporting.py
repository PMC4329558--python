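"""Multiple-testing thresholds, significance labels and output tables.

Three significance tiers are used downstream:

* Bonferroni: p below fwer / family size, with the SNP family counting
  distinct SNPs (a SNP mapped to two genes counts once);
* SNP report cut: p < 0.001 (the working SNP-level criterion when few SNPs
  clear Bonferroni);
* nominal: gene- or pathway-level p < 0.05.

All comparisons are strict. Thresholds are exact quotients; display uses
3 significant figures in scientific notation (round-half-even).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BonferroniFamily:
    """A named multiple-testing family with its exact threshold."""

    family_name: str
    family_size: int
    fwer: float = 0.05

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise ValueError(
                f"family {self.family_name!r}: size must be >= 1, "
                f"got {self.family_size}"
            )

    @property
    def threshold(self) -> float:
        return self.fwer / self.family_size

    @property
    def threshold_display(self) -> str:
        return format_sig3(self.threshold)


def bonferroni_threshold(family_size: int, fwer: float = 0.05) -> float:
    """Exact Bonferroni threshold fwer / family_size."""
    if family_size < 1:
        raise ValueError(f"family_size must be >= 1, got {family_size}")
    return fwer / family_size


def format_sig3(value: float) -> str:
    """3-significant-figure scientific notation, e.g. 3.52e-05.

    Python float formatting rounds half to even, matching the documented
    display convention.
    """
    return f"{value:.2e}"


def label_significance(
    gene_table: pd.DataFrame,
    snp_table: pd.DataFrame,
    snp_family: BonferroniFamily,
    gene_family: BonferroniFamily,
    nominal: float = 0.05,
    snp_report_cut: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach significance flags; all comparisons strict (<).

    ``gene_table`` needs a ``p_artp`` column; ``snp_table`` a ``p`` column.
    Returns labeled copies: genes gain ``sig_nominal``/``sig_bonferroni``,
    SNPs gain ``sig_report``/``sig_bonferroni``.
    """
    genes = gene_table.copy()
    genes["sig_nominal"] = genes["p_artp"] < nominal
    genes["sig_bonferroni"] = genes["p_artp"] < gene_family.threshold
    snps = snp_table.copy()
    snps["sig_report"] = snps["p"] < snp_report_cut
    snps["sig_bonferroni"] = snps["p"] < snp_family.threshold
    return genes, snps


def gene_summary_table(
    gene_table: pd.DataFrame,
    snp_table: pd.DataFrame,
    gene_snp_map,
    nominal: float = 0.05,
) -> pd.DataFrame:
    """Genes with ARTP p below the nominal cut, sorted ascending, each with
    its most significant SNP (by per-SNP p) and that SNP's p-value."""
    rows = []
    snps_by_gene = gene_snp_map.snps_by_gene if hasattr(
        gene_snp_map, "snps_by_gene") else gene_snp_map
    for gene, rec in gene_table.iterrows():
        if not rec["p_artp"] < nominal:
            continue
        snp_ids = [s for s in snps_by_gene.get(gene, []) if s in snp_table.index]
        best_snp, best_p = "", np.nan
        if snp_ids:
            sub = snp_table.loc[snp_ids, "p"].astype(float)
            best_snp = sub.idxmin()
            best_p = float(sub.min())
        rows.append(
            {
                "gene": gene,
                "p_artp": float(rec["p_artp"]),
                "n_snps": int(rec["n_snps"]),
                "top_snp": best_snp,
                "top_snp_p": best_p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene", "p_artp", "n_snps", "top_snp", "top_snp_p"]
    )
    return out.sort_values("p_artp", kind="stable").reset_index(drop=True)


def pathway_summary_row(
    name: str,
    n_genes: int,
    n_snps: int,
    covariates: list[str],
    pathway_p: float,
) -> dict:
    return {
        "analysis": name,
        "n_genes": n_genes,
        "n_snps": n_snps,
        "covariates": ",".join(covariates) if covariates else "none",
        "pathway_p": pathway_p,
    }


def write_manifest(path, **fields) -> None:
    """JSON run manifest (seed, thresholds, counts, versions)."""
    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v

    with open(path, "w") as fh:
        json.dump({k: _clean(v) for k, v in fields.items()}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
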