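# cmaf — ensemble drug–disease association prediction

`cmaf` predicts new therapeutic indications for existing drugs (drug
repositioning) from three inputs: a binary drug–disease association matrix
**Y** (m drugs × n diseases, Y_ij = 1 iff drug i is known to treat disease j),
a drug–drug similarity matrix in [0, 1] (e.g. Tanimoto scores of 2D chemical
fingerprints), and a disease–disease similarity matrix in [0, 1] (e.g.
phenotype text-mining similarity between OMIM entries). It is aimed at
computational biologists who have such matrices as labeled TSV files and want
ranked candidate indications plus a rigorous hold-out evaluation.

## The method

Four stages, each also exposed as a library function and a CLI subcommand:

1. **WKNKN completion.** Zero entries of Y are replaced by interaction
   likelihoods borrowed from each entity's K nearest *known* neighbors
   (entities with ≥ 1 association), weighted by `T^(i-1) · s_i` and
   normalized by `Σ s_i` (defaults K = 5, T = 0.5). Drug-side and
   disease-side estimates are averaged and merged as `max(Y, Y_rd)`, so new
   drugs and diseases get informative profiles and recorded positives are
   preserved.
2. **Linear neighborhood similarity.** For each entity, reconstruction
   weights over its K nearest neighbors (K = 100, capped at p − 1) solve the
   simplex-constrained QP `min ωᵀ(G + λI)ω, Σω = 1, ω ≥ 0` with
   `G[j,l] = (x_i − x_j)·(x_i − x_l)` and λ = 1; the stacked rows form a
   row-stochastic directed similarity graph S\*.
3. **Three base predictors.**
   * *LPRIA* — label propagation `Y_{t+1} = αS*Y_t + (1−α)Y⁰` solved in
     closed form `(1−α)(I − αS*)⁻¹Y⁰` (α = 0.5), run over drugs and over
     diseases and averaged;
   * *NMFRIA* — graph-regularized NMF `Y ≈ WHᵀ` minimizing
     `‖Y − WHᵀ‖²_F + λ_l(‖W‖²_F + ‖H‖²_F) + λ_r Tr(WᵀL_rW) + λ_d Tr(HᵀL_dH)`
     by multiplicative updates (k = 100, λ_l = 2, λ_r = λ_d = 1e-4);
   * *NCPRIA* — network consistency projection
     `Y***(i,j) = (S*_r(i,:)·Y(:,j)/‖Y(:,j)‖ + Y(i,:)·S*_d(:,j)/‖Y(i,:)‖) /
     (‖S*_r(i,:)‖ + ‖S*_d(:,j)‖)`, with exact zeros of Y replaced by 1e-30.
4. **Noisy-OR fusion.** `Rt = 1 − (1 − Y*)(1 − Y**)(1 − Y***)`, the final
   association probability (NMF scores clipped to [0, 1] first).

An evaluation harness (repeated 10-fold CV over known pairs, de-novo
whole-drug hold-out, ROC/AUC with half-credit ties) and a planted-structure
synthetic generator round out the package.

## Worked example

Generate a synthetic 40-drug × 25-disease network with 3 planted therapeutic
themes, run the full pipeline, cross-validate, and rank candidates:

```bash
cmaf simulate --drugs 40 --diseases 25 --rank 3 --density 0.12 --seed 11 -o sim
cat > run.toml <<'EOF'
association = "sim/associations.tsv"
drug_similarity = "sim/drug_similarity.tsv"
disease_similarity = "sim/disease_similarity.tsv"
output_dir = "out"
seed = 11
EOF
cmaf run run.toml          # writes completed.tsv, *_lns.tsv, scores_*.tsv, manifest.json
cmaf cv run.toml --method CMAF -o cv.json
cmaf rank out/scores_cmaf.tsv sim/associations.tsv --drug DR0003 --top 5
```

which prints:

```
CMAF CV AUC (grand mean): 0.9116
drug_id	disease_id	score	rank
DR0003	DS0022	0.9201172189704474	1
DR0003	DS0009	0.5937639123585974	2
DR0003	DS0021	0.4649019005946363	3
DR0003	DS0020	0.4358162429122828	4
DR0003	DS0007	0.429069824999048	5
```

The CV number is the grand mean over 10 repeats of 10-fold cross-validation:
in each fold the held-out known pairs are scored against all pairs unknown in
the full matrix, after re-running the entire pipeline on the training matrix
only. The ranked list shows the drug's top candidate diseases (known
associations excluded) with their fused association probabilities — on this
synthetic instance the top candidate is a same-theme disease whose
association was simply never sampled.

Real data plugs in the same way: labeled TSVs with DrugBank IDs as row labels
and OMIM IDs as column labels.

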