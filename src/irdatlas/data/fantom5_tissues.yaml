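# Built-in 13-group tissue aggregation scheme for the FANTOM5/Human Protein
# Atlas consensus bulk expression table. Each of the 53 enumerated tissue
# sample names maps to exactly one of 13 groups; retina is the target group
# for the retina-prevalence classifier.
target_group: retina
groups:
  brain_max:
    - amygdala
    - caudate
    - cerebellum
    - thalamus
    - hippocampus
    - nucleus accumbens
    - temporal cortex
    - pituitary gland
    - putamen
    - postcentral gyrus
    - spinal cord
    - substantia nigra
    - corpus callosum
    - frontal lobe
    - insular cortex
    - olfactory bulb
    - pons
    - occipital pole
    - occipital lobe
    - occipital cortex
    - medulla oblongata
    - medial temporal gyrus
    - medial frontal gyrus
  glands_max:
    - salivary gland
    - thyroid gland
    - thymus
  digestive_max:
    - colon
    - esophagus
    - small intestine
    - appendix
    - gallbladder
    - smooth muscle
  heart:
    - heart muscle
  liver:
    - liver
  lung:
    - lung
  pancreas:
    - pancreas
  muscle:
    - skeletal muscle
  lymph_node:
    - lymph node
  diversive_max:
    - prostate
    - spleen
    - tongue
    - urinary bladder
    - adipose tissue
    - breast
    - cervix
    - endometrium
    - ovary
    - vagina
    - placenta
    - seminal vesicle
  testis:
    - testis
  kidney:
    - kidney
  retina:
    - retina
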