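"""Extract the 24-element morphometric feature vector from one phantom.

Per region (zona pellucida, trophectoderm, inner area) the extractor
computes area and perimeter in micrometres, mean/SD of pixel intensity,
mean/SD of the local-entropy texture map (bits), and the length and
density of Canny edges — 8 features x 3 regions = 24.
"""
from blastomorph import PhantomSpec, extract_features, generate_phantom

sample = generate_phantom(PhantomSpec(), seed=42)
fv = extract_features(sample.micrograph, sample.masks)

for name, value in fv.to_dict().items():
    print(f"{name:24s} {value:10.3f}  [{fv.units[name]}]")

print("\nZP ring area above reflects an ~180 um embryo with an "
      f"~18 um zona; entropy values near {fv['mean_entropy_te']:.1f} bits "
      "in the trophectoderm quantify its speckled texture.")
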