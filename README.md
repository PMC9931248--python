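# avgrade

Automated grading of retinal arteriolosclerosis at arterio-venous (A/V)
crossings, for researchers building computer-aided screening tools from
fundus photographs.

Arteriolosclerosis — hardening of the small arteries — deforms retinal veins
where an artery crosses over them, and Scheie's classification grades the
deformation in four steps by how strongly the venular caliber narrows at the
crossing edges: *none*, *mild* (slight narrowing at both venular edges),
*moderate* (strong narrowing at one edge) and *severe* (strong narrowing at
both edges). Grading these crossings by eye takes vast experience and
reproduces poorly, which makes it a natural target for automation.

`avgrade` implements the full diagnostic chain as a library plus a thin CLI:

1. **Preprocessing** (`avgrade.prep`) — reconcile noisy per-pixel artery/vein
   labels with the (more reliable) vessel segmentation: labels are clipped to
   the vessel mask and homogenized per vessel segment by majority vote, with
   segments delimited by skeleton branch points.
2. **Candidate detection** (`avgrade.detect`) — artery pixels touching vein
   pixels are clustered into contact candidates; a skeleton-traversal check
   on a disc around each candidate rejects T-junctions (a vessel merely
   ending on another); candidates in the optic-cup zone, where segmentation
   is unreliable, are excluded. A 150×150 patch is cut around each survivor.
3. **Validation** — a CNN classifier decides whether a patch shows a true,
   diagnostically usable crossing (artery passing *over* the vein). Only the
   artery-over-vein configuration carries the grading signal.
4. **Severity grading** (`avgrade.models`) — a *multi-diagnosis team
   network* (MDTNet): sub-models trained independently with cross-entropy
   (base module) and with focal losses of increasing focusing strength
   γ = 1..n (focal module); their penultimate-layer features are concatenated
   and a two-layer fusion head, trained on the frozen features, makes the
   final call.

The focal loss for softmax output *y* and one-hot target *t* is

    L(y, t) = − Σ_l α_l · t_l · (1 − y_l)^γ · log y_l ,

which reduces to (weighted) cross-entropy at γ = 0; larger γ focuses
training on hard samples. Class imbalance — *none* dominates while *severe*
is rare — is softened by the sub-linear log-ratio weights
α_l = ln N_l / ln N, computed from training-split class counts. Ensembling
over several γ values sidesteps tuning γ, which the loss is notoriously
sensitive to.

Because the cohort data such pipelines are trained on is private, the
package ships a synthetic scene generator (`avgrade.synthetic`) that plants
crossings with known z-order and grade morphology (caliber-narrowing factors
per venular edge), so every stage is testable against exact ground truth.
All neural components run on a small, deterministic numpy CNN toolkit
(`avgrade.nn`) — no GPU needed.

## Worked example

Detect planted crossings on 20 synthetic scenes
(`examples/02_detect_crossings.py`):

```
planted crossings: 60, detected candidates: 60
recall    0.983
precision 0.983
```

Class weighting for a grading corpus with counts (1177, 816, 457, 57)
(`examples/03_focal_loss_weights.py`):

```
class counts (1177, 816, 457, 57), N = 2507
  alpha_none      = ln 1177 / ln 2507 = 0.9034
  alpha_mild      = ln  816 / ln 2507 = 0.8566
  alpha_moderate  = ln  457 / ln 2507 = 0.7825
  alpha_severe    = ln   57 / ln 2507 = 0.5166
```

Train a small grading team on clearly separable synthetic grades
(`examples/04_train_grading_team.py`, a couple of minutes on one CPU):

```
patches: 320 train / 40 val / 40 test
sub-model (gamma=0) test accuracy: 1.000
sub-model (gamma=1) test accuracy: 0.950
fused team test accuracy: 1.000, kappa: 1.000
```

The fused decision matches or beats the best single sub-model, and the
sub-models' weights are bit-identical before and after fusion training —
only the head learns.

The CLI mirrors these stages: `avgrade simulate`, `detect`,
`train-submodel`, `train-fusion`, `predict`, `run`, `evaluate`, `explain`.
`avgrade run` persists every intermediate (refined maps, skeletons,
candidate tables, patches) next to its JSON report, so each step of a
diagnosis can be audited; rerunning with the same configuration and seed
reproduces the report byte-for-byte.

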