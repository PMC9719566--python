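# mirrornet

Can a neural network *learn* what bilateral symmetry is — and apply it to
images unlike anything it was trained on? `mirrornet` is a self-contained
laboratory for that question, aimed at researchers in computational
neuroscience and vision. It generates synthetic 20x20 gray-level stimulus
families in which mirror symmetry is the only informative feature, trains
two small classifiers from scratch — a three-cell **convolutional LSTM**
(recurrent) and a **dilated-convolution network** (feed-forward, with a
receptive field larger than the image) — and measures whether each has
learned the general rule or a local shortcut.

An image `I` (20x20, gray levels 0-255) is *symmetric* iff its left flank
equals the column-reversed right flank exactly:

    I[r, c] = I[r, 19 - c]   for all flank columns c,

with an uninformative central band (constant 128) of width
`b in {0, 2, 4, 6, 14, 16, 18}` separating the flanks, or — in the Stripe
families — all information confined to the single mirror column pair
`(x, 19 - x)`. Training uses only `b in {0, 4}`; every other family is out
of distribution. The analyses around the classifiers:

* cross-dataset accuracy per held-out family;
* a time-step sweep — accuracy of the recurrent net when inference is
  truncated to `s in {5, 10, 20, 30, 50}` unrolling steps, which reveals a
  learned *visual routine* that propagates information outward from the
  midline (distant stripes need more steps);
* the *degree of non-symmetry* `r = corr(left flank, flipped right flank)`
  and misclassification histograms over it;
* representational similarity analysis: cosine-distance RDMs of the
  pre-readout layer compared (masked Pearson) with six prototype RDMs
  (Symmetry-1/2, Symmetry-Small-Band, Band-Presence, Brightness,
  Band-Width);
* k-means summarisation of last-cell activation maps into centroid grids.

The numerical core (im2col convolutions, backpropagation through time,
Adam) is implemented directly on numpy/BLAS and verified against scipy
convolution oracles and finite differences; see `docs/methods.md`.

## Worked example

Train the scaled-down recurrent classifier on the Band{0,4} corpus and
probe it on held-out families (about 14 minutes on one CPU):

```python
from mirrornet import ConvLSTMClassifier, FamilySpec, generate_family, make_training_corpus
from mirrornet.evaluation import evaluate, timestep_sweep

corpus = make_training_corpus(n_total=6000, split_fraction=0.05, seed=0)
clf = ConvLSTMClassifier(n_channels=8, unroll_steps=50, learning_rate=1e-3,
                         max_epochs=2, validation_fraction=0.0, random_state=0)
clf.fit(corpus.train_images, corpus.train_labels,
        X_val=corpus.val_images, y_val=corpus.val_labels)
print("validation accuracy:", clf.best_validation_accuracy_)

for b in (4, 14, 18):  # band 4 seen in training; 14 and 18 never seen
    fam = generate_family(FamilySpec("band", band_size=b), 1000, seed=100 + b)
    print(f"band {b:2d}: {evaluate(clf, fam):.3f}")

far = generate_family(FamilySpec("stripe", stripe_x=2), 1000, seed=902)
print(timestep_sweep(clf, far, [5, 10, 20, 30, 50]))
```

Output from one run of this snippet:

```
validation accuracy: 1.0
band  4: 0.995
band 14: 0.976
band 18: 0.972
   steps  accuracy   family
0      5     0.500  stripe2
1     10     0.500  stripe2
2     20     0.500  stripe2
3     30     0.635  stripe2
4     50     0.977  stripe2
```

Reading: the recurrent net transfers the symmetry rule to bands it never
saw (~0.95-0.98 vs. the 0.50 chance level that the feed-forward dilated
net scores there), and the stripe pair farthest from the midline is only
solved once inference is given ~50 unrolling steps — the signature of a
step-by-step outward comparison routine. A model trained with short
unrolls (T <= 20) instead learns a near-midline shortcut: perfect
validation accuracy, chance on large bands.

The same pipeline is scriptable end to end:

```bash
mirrornet run-all --preset scaled_down --seed 0 --out runs/demo
mirrornet sweep-steps --model runs/demo/train/lstm3.npz --family stripe8 --steps 5,10,20,30,50
```

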