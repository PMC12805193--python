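"""Criteria on a toy instance, and the identity linking k-means to diversity.

Builds the 4-object toy dissimilarity matrix used throughout the docs and
scores the three partitions into two pairs, then shows on random data that
the k-means (centroid) criterion equals the average diversity computed on
squared Euclidean distances.
"""

import numpy as np

from anticlustering import (
    Partition,
    average_diversity,
    dispersion,
    diversity,
    kmeans_criterion,
    partition_count,
    random_partition,
    squared_euclidean_matrix,
)

D = np.zeros((4, 4))
for (i, j), v in {(0, 1): 1, (0, 2): 2, (0, 3): 3,
                  (1, 2): 4, (1, 3): 5, (2, 3): 6}.items():
    D[i, j] = D[j, i] = float(v)

print("partitions of 4 objects into 2 pairs:", partition_count(4, 2))
for labels in ([0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 1, 0]):
    part = Partition(np.array(labels))
    print(
        f"  {labels}: diversity={diversity(D, part):.0f} "
        f"dispersion={dispersion(D, part):.0f}"
    )
# All three partitions tie on diversity (7), but only {14|23} achieves
# dispersion 3: its most-similar within-group pair is the least similar.

rng = np.random.default_rng(0)
X = rng.normal(size=(12, 3))
DX = squared_euclidean_matrix(X).values
C = random_partition(12, [4, 4, 4], rng)
print("\nk-means criterion      :", round(kmeans_criterion(X, C), 6))
print("average diversity (sq.):", round(average_diversity(DX, C), 6))
# Identical: centroid-based and pairwise-distance-based computations of the
# same between-group balance objective.
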