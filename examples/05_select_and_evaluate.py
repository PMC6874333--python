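"""The full harness: rank features on a small feature-selection subset, train
a random forest on the full training data, evaluate on held-out samples.

This mirrors the nested design of a biomarker study: feature selection may
only see a fraction of the training cohort (the FSDS), and the question is
which ranking method survives that starvation best.
"""

from nbbd import (build_proxi, experiment_grid, make_benchmark, ntps_score,
                  split_by_phenotype, summarize_top, GeneratorParams)
from nbbd.benchmark import log_counts
from nbbd.selection import hybrid_score, rffi, select_top_k

bench = make_benchmark(GeneratorParams(seed=21))
train = bench.table
# independent test cohort drawn from the same latent truth graphs
test = bench.resample(n_per_group=100, seed=9000)


def ntps_selector(fsds, k, seed):
    a, b = split_by_phenotype(fsds)
    scores = ntps_score(build_proxi(log_counts(a)), build_proxi(log_counts(b)), "btw")
    return select_top_k(scores, min(k, len(scores))).ranked_taxa


def rffi_selector(fsds, k, seed):
    return select_top_k(rffi(fsds, n_trees=200, seed=seed), k).ranked_taxa


def hybrid_selector(fsds, k, seed):
    a, b = split_by_phenotype(fsds)
    ntps = ntps_score(build_proxi(log_counts(a)), build_proxi(log_counts(b)), "btw")
    scores = hybrid_score(rffi(fsds, n_trees=200, seed=seed), ntps)
    return select_top_k(scores, min(k, len(scores))).ranked_taxa


methods = {"rffi": rffi_selector, "ntps_btw": ntps_selector,
           "hybrid": hybrid_selector}
grid = experiment_grid(train, test, fsds_sizes=[25, 100], methods=methods,
                       k_grid=[10, 20, 40], n_trees=200, seed=5)
top = summarize_top(grid)
cols = ["fsds", "method", "n_features", "acc", "sn", "sp", "mcc", "auc"]
print(top[cols].to_string(index=False,
                          float_format=lambda v: f"{v:.2f}"))
print("\neach row: the best (highest AUC, then fewest features) classifier "
      "per feature-selection method and FSDS size; 'none' = all 100 taxa")
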