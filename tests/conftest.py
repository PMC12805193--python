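import numpy as np
import pytest

from anticlustering import Partition, dispersion, diversity, average_diversity


@pytest.fixture
def d4():
    """Toy 4-object instance: d12=1, d13=2, d14=3, d23=4, d24=5, d34=6."""
    D = np.zeros((4, 4))
    for (i, j), v in {(0, 1): 1, (0, 2): 2, (0, 3): 3,
                      (1, 2): 4, (1, 3): 5, (2, 3): 6}.items():
        D[i, j] = D[j, i] = float(v)
    return D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, N, P=2, sd=1.0):
    """Random feature data and its squared-Euclidean dissimilarities."""
    from anticlustering import squared_euclidean_matrix

    X = rng.normal(0.0, sd, size=(N, P))
    return X, squared_euclidean_matrix(X).values


def reference_bpi(Ddiv, Ddisp, w, assign, K, use_avg=False):
    """Pure-Python best-improvement pairwise interchange (independent oracle).

    Recomputes both criteria from scratch for every candidate swap; same
    acceptance rule and tie-breaking as the production kernel: best strictly
    improving partner per focal object, ties to the lowest partner index.
    """
    assign = np.asarray(assign).copy()

    def objective(a):
        part = Partition(a, K=K)
        div = average_diversity(Ddiv, part) if use_avg else diversity(Ddiv, part)
        disp = dispersion(Ddisp, part)
        obj = w * div
        if w < 1.0 and np.isfinite(disp):
            obj += (1.0 - w) * disp
        return obj, div, disp

    N = len(assign)
    moves = []
    for _ in range(10000):
        improved = False
        for i in range(N):
            cur_obj, _, _ = objective(assign)
            tol = 1e-9 * (1.0 + abs(cur_obj))
            best_gain, best_j = tol, -1
            for j in range(N):
                if assign[j] == assign[i]:
                    continue
                trial = assign.copy()
                trial[i], trial[j] = trial[j], trial[i]
                obj, _, _ = objective(trial)
                if obj - cur_obj > best_gain:
                    best_gain, best_j = obj - cur_obj, j
            if best_j >= 0:
                assign[i], assign[best_j] = assign[best_j], assign[i]
                moves.append((i, best_j))
                improved = True
        if not improved:
            break
    return assign, moves
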