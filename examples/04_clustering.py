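"""Clustering epigenetic features and AS types from the signed matrix.

Builds a signed log10-p matrix with four planted feature archetypes and
an opposite-sign structure between the exon-skipping types (ES, ME) and
the splice-site-selection types (A3SS, A5SS, IR), then runs seeded
k-means (k=4 over features, k=2 over AS types) and a classical MDS
embedding of the feature rows.
"""

import numpy as np
import pandas as pd

from episplice.as_annotation import EVENT_TYPES
from episplice.clustering import classical_mds, cluster_as_types, kmeans_cluster
from episplice.profiling import BIN_IDS

rng = np.random.default_rng(4)
cols = pd.MultiIndex.from_product([EVENT_TYPES, BIN_IDS], names=["event_type", "bin"])

archetypes = rng.normal(scale=8.0, size=(4, 20))
rows, names = [], []
for k in range(4):
    for i in range(3):
        rows.append(archetypes[k] + rng.normal(scale=0.5, size=20))
        names.append(f"mark{k}{chr(97 + i)}")
matrix = pd.DataFrame(rows, index=names, columns=cols)
# impose the ESRP/ASSP sign structure on top of the archetypes
for etype in ("ES", "ME"):
    matrix[etype] = -matrix[etype].abs()
for etype in ("A3SS", "A5SS", "IR"):
    matrix[etype] = matrix[etype].abs()

feat = kmeans_cluster(matrix, k=4, seed=0)
print("feature clusters (k=4):")
for label, items in feat.groups().items():
    print(f"  cluster {label}: {', '.join(items)}")

types = cluster_as_types(matrix, k=2, seed=0)
print("\nAS-type classes (k=2):")
for label, items in types.groups().items():
    print(f"  class {label}: {', '.join(items)}")
# The two classes separate the exon-skipping-related process (ES, ME)
# from the alternative splice-site-selection process (A3SS, A5SS, IR).

emb = classical_mds(matrix, dims=2)
print("\nclassical MDS of features (first rows):")
print(emb.head(4).round(2).to_string())
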