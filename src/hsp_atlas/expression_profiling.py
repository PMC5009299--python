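"""Expression summaries: RPKM matrices, 2^-ddCt qPCR fold changes,
PCR efficiency, and log-transformed heat-map matrices.

RPKM = 1e9 * C / (N * L) with C mapped reads for the gene, N the
library size (total mapped reads) and L the gene length in bp.  qPCR
fold changes follow the 2^-ddCt method: technical replicates are
averaged per biological replicate, biological replicates averaged per
group, dCt is taken against the reference gene (Act2 by default), and
ddCt against the control condition of the same cultivar, tissue and
timepoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def rpkm_matrix(
    counts: pd.DataFrame,
    lengths: pd.Series | dict[str, int],
    library_sizes: pd.Series | dict[str, float],
) -> pd.DataFrame:
    """Reads-per-kilobase-per-million matrix (genes x samples)."""
    lengths = pd.Series(lengths, dtype=float)
    library_sizes = pd.Series(library_sizes, dtype=float)
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise KeyError(f"genes without length: {sorted(missing)[:5]}")
    if (lengths.loc[list(counts.index)] <= 0).any():
        raise ValueError("gene lengths must be positive")
    missing_lib = set(counts.columns) - set(library_sizes.index)
    if missing_lib:
        raise KeyError(f"samples without library size: {sorted(missing_lib)}")
    if (library_sizes.loc[list(counts.columns)] <= 0).any():
        raise ValueError("library sizes must be positive")
    L = lengths.loc[counts.index].to_numpy()[:, None]
    N = library_sizes.loc[counts.columns].to_numpy()[None, :]
    return pd.DataFrame(
        1e9 * counts.to_numpy(dtype=float) / (N * L),
        index=counts.index,
        columns=counts.columns,
    )


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str = "Act2",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Fold changes per (gene, cultivar, tissue, condition, timepoint).

    ``ct_table`` needs columns gene_id, cultivar, tissue, condition,
    timepoint, bio_rep, tech_rep, ct.  Returns one row per treated
    group with delta_ct, delta_delta_ct and fold = 2^-ddCt.
    """
    required = {"gene_id", "cultivar", "tissue", "condition", "timepoint", "bio_rep", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns {sorted(missing)}")
    group_keys = ["cultivar", "tissue", "condition", "timepoint"]
    # technical -> biological -> group mean Ct
    per_bio = (
        ct_table.groupby(group_keys + ["gene_id", "bio_rep"], as_index=False)["ct"].mean()
    )
    per_group = per_bio.groupby(group_keys + ["gene_id"], as_index=False)["ct"].mean()
    ref = per_group[per_group["gene_id"] == reference_gene].set_index(group_keys)["ct"]
    targets = per_group[per_group["gene_id"] != reference_gene]
    rows = []
    for _, row in targets.iterrows():
        key = tuple(row[k] for k in group_keys)
        if key not in ref.index:
            raise ValueError(
                f"reference gene {reference_gene!r} missing for group {key}"
            )
        rows.append({**{k: row[k] for k in group_keys},
                     "gene_id": row["gene_id"],
                     "delta_ct": row["ct"] - float(ref.loc[key])})
    dct = pd.DataFrame(rows)
    controls = dct[dct["condition"] == control_condition].set_index(
        ["cultivar", "tissue", "timepoint", "gene_id"]
    )["delta_ct"]
    treated = dct[dct["condition"] != control_condition]
    out_rows = []
    for _, row in treated.iterrows():
        key = (row["cultivar"], row["tissue"], row["timepoint"], row["gene_id"])
        if key not in controls.index:
            raise ValueError(f"no {control_condition!r} group for {key}")
        ddct = row["delta_ct"] - float(controls.loc[key])
        out_rows.append({
            "gene_id": row["gene_id"], "cultivar": row["cultivar"],
            "tissue": row["tissue"], "condition": row["condition"],
            "timepoint": row["timepoint"],
            "delta_ct": row["delta_ct"], "delta_delta_ct": ddct,
            "fold": 2.0 ** (-ddct),
        })
    return pd.DataFrame(
        out_rows,
        columns=["gene_id", "cultivar", "tissue", "condition", "timepoint",
                 "delta_ct", "delta_delta_ct", "fold"],
    )


def pcr_efficiency(slope: float) -> float:
    """Amplification efficiency from a dilution-series slope.

    efficiency = 10^(-1/slope) - 1; a slope of -3.32 corresponds to a
    perfect doubling (efficiency 1.0).
    """
    if slope >= 0:
        raise ValueError("dilution-series slope must be negative")
    return 10.0 ** (-1.0 / slope) - 1.0


def heatmap_matrix(values: pd.DataFrame, transform: str = "log2p1") -> pd.DataFrame:
    """Log-transformed matrix for heat-map display.

    ``log2p1``: log2(x + 1) for expression values (x >= 0).
    ``log10ct``: log10(x) for raw Ct values (x > 0).
    """
    arr = values.to_numpy(dtype=float)
    if transform == "log2p1":
        if (arr < 0).any():
            raise ValueError("negative values in log2p1 mode")
        out = np.log2(arr + 1.0)
    elif transform == "log10ct":
        if (arr <= 0).any():
            raise ValueError("non-positive Ct values in log10ct mode")
        out = np.log10(arr)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def save_heatmap_image(matrix: pd.DataFrame, path: str) -> None:
    """Optional PNG rendering of a heat-map matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1]), max(4, 0.12 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
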