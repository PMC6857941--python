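# ugtcap

Predicting the glucuronidation capacity of UGT1A1 variants from docking
poses.

UGT1A1 detoxifies bilirubin, estradiol, acetaminophen and the irinotecan
metabolite SN-38 by transferring glucuronic acid from the coenzyme UDPGA
onto a substrate hydroxyl. Sequencing finds new coding variants faster than
assays can characterise them, yet a variant's conjugation capacity decides
drug-toxicity risk (e.g. irinotecan dosing). `ugtcap` is for structural
bioinformaticians who already have docking output: it classifies poses by a
geometric criterion for catalytic competence, fits a sigmoid model linking
pose statistics to measured capacity, and predicts unmeasured variants with
leave-one-out validation.

## The model

A docking pose is **hydroxyl-oriented** when a substrate hydroxyl oxygen
lies within 3.8 Å (a 3.2 Å hydrogen bond + 0.6 Å docking error) of the
midpoint of UDPGA's glycosidic C–O bond. With S_DH oriented poses out of
S_DT runs, capacity is

    P_c = σ · κ · [ 1 / (1 + e^(−γ(S_DH/S_DT − μ)) ) ]^β + ε,   β = S_DT / S_DH(wild)

where σ scales the substrate, γ and μ shape the sigmoid, ε (0 in vitro) is
an environment offset, and κ = 1.0 / 0.74 / 0.21 rescales for the *28
promoter genotype (ratios of Vmax 16.2 / 12.0 / 3.4 nmol·min⁻¹·mg⁻¹).
(σ, γ, μ) are fitted by least squares against in vitro capacities over the
variants with known capacity and a correctly bound coenzyme; relative
capacity is 100·κ·S(mutant)/S(wild). See `docs/methods.md` for details.

## Worked example

Generate a synthetic study (poses with planted labels plus two model-drawn
variant panels), classify, fit, and cross-validate:

```
python analysis/01_simulate.py
python analysis/02_classify.py
python analysis/03_fit.py
python analysis/04_cross_validate.py
```

which prints:

```
docking campaign: 100 poses, 30 planted oriented -> results/synthetic/poses/substrate_poses.pdbqt
...
S_DH = 30 / S_DT = 100 at cutoff 3.8 A; coenzyme correct binding in 1/1 runs
agreement with planted labels: 100/100 poses (exact)
panel_noise_free: sigma=50.0000 gamma=8.0000 mu=0.4000 (beta=2.50 fixed by wild counts) SSE=6.336e-29
panel_noisy: sigma=50.2777 gamma=8.0573 mu=0.4029 (beta=2.50 fixed by wild counts) SSE=3.675
panel_noise_free: LOO Pearson r = 1.0000 (n = 21, p = 2.23e-308)
panel_noisy: LOO Pearson r = 0.9997 (n = 21, p = 4.75e-32)
```

Reading: the classifier reproduces every planted orientation label; the
fitter recovers the generating constants (σ=50, γ=8, μ=0.4) exactly on the
clean panel and within 0.8% under 5% assay noise; and held-out variants are
predicted at r ≈ 1, i.e. the model cross-validates on data that follow its
own assumptions. Tables land under `results/`.

The same steps run on real data from the shell:

```
ugtcap classify --receptor rec.pdbqt --udpga-poses udpga.pdbqt \
    --substrate-poses sub.pdbqt --cutoff 3.8 --min-contacts 5 --out poses.csv
ugtcap fit --summaries summaries.csv --capacities capacities.csv \
    --ligand AAP --seed 17 --out aap_params.yaml
ugtcap predict --summaries summaries.csv --params aap_params.yaml --out pred.csv
ugtcap cv --summaries summaries.csv --capacities capacities.csv \
    --ligand AAP --seed 17 --out cv.csv
```

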