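# cellsignal

Quantify single-cell-derived mRNA signals in bulk RNA-seq transcriptomes.

Bulk tumor transcriptomes are mixtures of cellular transcriptional programs
— the tumor cells themselves, their normal cell correlates, stroma, vessels,
immune infiltrate. Given reference expression *signals* built from annotated
single-cell data, `cellsignal` estimates how much of each signal is present
in a bulk sample, **without assuming the reference is complete**: an explicit
intercept absorbs whatever the reference cannot explain, and its normalized
share is reported as the *unexplained signal*. This makes the method suited
to questions like "how much fetal-kidney signal does this Wilms tumor carry?"
where forcing the composition to sum to 1 over an incomplete reference would
silently misattribute the mismatch.

## The model

A reference signal is a cell population's expression profile: raw counts
summed over the population's cells and normalized so that Σ_g s_gc = 1.
For each bulk sample *p* with fragment counts *y_gp* and effective gene
lengths *l_gp*, the model is

    λ_gp  = Σ_c s_gc · β_cp + β_0p        (β_cp = e^{z_cp} > 0)
    λ'_gp = λ_gp · l_gp
    y_gp ~ Poisson(λ'_gp)

fitted by minimizing the weighted negative log-likelihood
Σ w_g (λ'_gp − y_gp log λ'_gp) over the latent z with Adam, with a
two-condition stop: the fractional change of both the likelihood and of
Q = Σ σ(z_cp) — a soft count of active signals — must fall below tolerance.
A Poisson likelihood suffices even though individual cellular signals are
negative-binomial: the over-dispersion of a sum of NB components shrinks
roughly as 1/N (see `cellsignal.compound`).

After the fit, the intercept is converted to the exposure of an equivalent
flat signal (profile 1/m per gene) and all exposures are normalized to sum
to 1 per sample; goodness of fit is McFadden's pseudo-R²
(1 − NLL_full / NLL_intercept-only). The companion single-cell scorer trains
offset-corrected one-vs-rest elastic-net logistic models (alpha = 0.99,
cross-validated strength by the one-standard-error rule) and reports raw
logit similarities — deliberately unnormalized, so a query population absent
from the reference scores low everywhere and is called "undecided".

## Worked example

`examples/quantify_pseudobulk.py` simulates a five-population single-cell
reference, mixes pseudo-bulk transcriptomes at known proportions, and fits
them:

```
Recovered signal fractions (first 5 pseudo-bulks):
        type_0  type_1  type_2  type_3  type_4  unexplained
bulk_0   0.047   0.078   0.183   0.254   0.435        0.003
bulk_1   0.472   0.087   0.061   0.178   0.202        0.001
...
Mean absolute error vs truth: 0.0005
Median pseudo-R2: 0.969
```

Each row is one bulk sample; the fractions sum to 1 and are the relative
contribution of each reference signal, with `unexplained` the intercept's
share. With a matched reference the error against the true mixing
proportions is ~5×10⁻⁴ per entry and the unexplained share is negligible.
Withholding a population from the reference
(`examples/unexplained_signal.py`) flips this: bulks made purely of the
withheld population come back with median unexplained ≈ 1.0 and pseudo-R²
≈ 0, the method's signature for "your reference does not contain this
transcriptome".

Other examples: `annotate_cells.py` (logit similarity annotation with a
novel query population), `immaturity_and_roc.py` (immaturity score, normal
reference range, ROC), `compound_poisson.py` (compound-NB moment matching).
A thin CLI mirrors the library: `cellsignal simulate | build-ref | fit |
similarity | score`.

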