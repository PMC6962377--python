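import numpy as np
import pandas as pd
import pytest

from mechanomir.interaction import InteractionMatrix


@pytest.fixture
def toy_label_mask():
    """A 100x120 mask: a 40x10 rectangle, a disk, and a border-touching blob."""
    mask = np.zeros((100, 120), dtype=int)
    mask[30:40, 20:60] = 1  # 10 rows x 40 cols rectangle
    yy, xx = np.mgrid[:100, :120]
    mask[(yy - 70) ** 2 + (xx - 90) ** 2 <= 12**2] = 2  # disk, r=12
    mask[0:8, 100:115] = 3  # touches the top border
    return mask


@pytest.fixture
def toy_exports():
    """Three miRNAs x two pathways of known targets."""
    rows = []
    for m in ("hsa-mir-1", "hsa-mir-2", "hsa-mir-3"):
        rows.append({"mirna": m, "pathway": "cell projection morphogenesis",
                     "database": "GO-BP", "enrichment_p": 0.01,
                     "targets": frozenset({"A", "B", "C", "D"})})
        rows.append({"mirna": m, "pathway": "pathways in cancer",
                     "database": "KEGG", "enrichment_p": 0.2,
                     "targets": frozenset({"C", "D", "E"})})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_de_map():
    return {"A": 3.0, "C": -2.5}


def make_matrix_from_values(values_by_group):
    """Build a minimal InteractionMatrix whose nodes carry given metric values.

    ``values_by_group``: mapping group label -> list of percent_overlap values
    (cumulative_abs_fc mirrors them).  Used to test aggregation/comparison in
    isolation from the scoring path.
    """
    rows = []
    i = 0
    for group, vals in values_by_group.items():
        for v in vals:
            rows.append({
                "mirna": f"m{i}", "pathway": f"p{i}", "group": group,
                "database": "KEGG", "intersects": True, "n_targets": 10,
                "n_de_targets": int(v / 10), "percent_overlap": float(v),
                "cumulative_abs_fc": float(v),
            })
            i += 1
    nodes = pd.DataFrame(rows)
    return InteractionMatrix(
        nodes=nodes,
        mirna_order=sorted(nodes["mirna"].unique()),
        pathway_order=sorted(nodes["pathway"].unique()),
        pathway_groups=dict(zip(nodes["pathway"], nodes["group"])),
    )
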