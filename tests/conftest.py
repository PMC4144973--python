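import numpy as np
import pytest

from tagdge import (
    build_tag_index,
    generate_transcriptome,
    simulate_expression,
    simulate_tag_library,
)


@pytest.fixture(scope="session")
def small_transcriptome():
    return generate_transcriptome(40, length_range=(100, 400), seed=101)


@pytest.fixture(scope="session")
def small_truth(small_transcriptome):
    return simulate_expression(
        small_transcriptome, de_fraction=0.2, effect_log2fc=2.0, seed=102
    )


@pytest.fixture(scope="session")
def small_index(small_transcriptome):
    return build_tag_index(small_transcriptome)


@pytest.fixture(scope="session")
def small_library(small_transcriptome, small_truth):
    return simulate_tag_library(
        small_transcriptome,
        small_truth,
        depth=20_000,
        error_rate=0.01,
        seed=103,
        cultivar="X",
        condition="exposure",
    )


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(ca != cb for ca, cb in zip(a, b))


def brute_force_digest(sequence: str) -> str:
    """Independent oracle: scan every position for the 3'-most qualifying CATG."""
    best = -1
    for i in range(len(sequence) - 20):
        if sequence[i : i + 4] == "CATG":
            best = i
    return sequence[best : best + 21] if best >= 0 else ""


def brute_force_map(tag_counts, index):
    """Oracle for map_tags: full Hamming-distance matrix, tiered resolution.

    Mismatches in the 4-nt anchor are not eligible at the 1-mismatch tier.
    """
    counts = {g: 0 for g in index.canonical_tag_by_gene}
    unmapped = ambiguous = 0
    for tag, count in tag_counts.items():
        exact = [g for g, t in index.canonical_tag_by_gene.items() if t == tag]
        if exact:
            hits = exact
        else:
            hits = [
                g
                for g, t in index.canonical_tag_by_gene.items()
                if hamming(t, tag) == 1 and t[:4] == tag[:4]
            ]
        if len(hits) == 1:
            counts[hits[0]] += count
        elif len(hits) > 1:
            ambiguous += count
        else:
            unmapped += count
    return counts, unmapped, ambiguous


def brute_force_average_linkage(points):
    """Oracle for cluster_ratios: recompute every inter-cluster average
    distance from the raw points at every step; lowest-id pair breaks ties."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    steps = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = float(
                    np.mean(
                        [
                            np.linalg.norm(points[p] - points[q])
                            for p in clusters[a]
                            for q in clusters[b]
                        ]
                    )
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        steps.append(((a, b), d))
        next_id += 1
    return steps


def ac_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Exact summation of the conditional point-mass series in log space."""
    from scipy.special import gammaln

    r = n2 / n1
    upper_limit = max(4000, int((x + 1) * r * 4) + 200, y + 200)
    ys = np.arange(0, upper_limit)
    logpmf = (
        ys * np.log(r)
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * np.log1p(r)
    )
    pmf = np.exp(logpmf)
    lower = pmf[: y + 1].sum()
    upper = pmf[y:].sum()
    return min(1.0, 2.0 * min(lower, upper))
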