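"""Full pipeline: OPNMF stability arm + PCA/EFA arm on a sample with
gender-like subgroups, plus cross-method and cross-subgroup agreement tables.

Uses a reduced split count so the example runs in seconds; the analysis
default is 10,000 split halves.
"""

from opnmfkit import AnalysisConfig, run_full_analysis

config = AnalysisConfig.from_dict(dict(
    seed=11,
    synthetic={"kind": "subgroups",
               "groups": [["M", 101, 0.0], ["F", 233, 0.0]],
               "p": 17, "k": 2, "noise_sd": 0.3},
    rank_range=(2, 6),
    n_splits=25,
    subgroups=[{"label": "male", "column": "group", "op": "eq", "value": "M"},
               {"label": "female", "column": "group", "op": "eq", "value": "F"}],
    pa_settings={"n_sim": 300, "percentile": 95.0},
))
report = run_full_analysis(config)

for name, res in report["samples"].items():
    print(f"{name:>7}: OPNMF k*={res['opnmf']['k_star']}  "
          f"PCA retains {res['pca']['k']}  EFA retains {res['efa']['k']} "
          f"(TLI {res['efa']['tli']:.3f})")

ari = report["comparisons"]["methods_full"]["ari"]
print("\ncross-method partition agreement on the full sample (ARI, 1 = same"
      " item grouping):")
print(ari.round(2).to_string())
ari_s = report["comparisons"]["samples_opnmf"]["ari"]
print("\nOPNMF partition agreement across subgroups:")
print(ari_s.round(2).to_string())
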