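# Built-in retinal cell-type scheme: 53 cell/cell-subtype columns collapsed
# into 19 major groups, plus 5 broader groups defined as unions of major
# groups (19 + 5 = 24 candidate specificity categories).
#
# SYNTHETIC RECONSTRUCTION: the published per-cell-type table names its 53
# subtype columns, but no authoritative list of those names is bundled here;
# the subtype names and their per-group multiplicities below are a plausible
# reconstruction from the adult human peripheral retina literature. Replace
# this file (or pass --scheme) to match the column names of a real table.
major_groups:
  Rods:
    - Rods
  Cones:
    - L/M cone
    - S cone
  RPE:
    - RPE
  Horizontal cells:
    - H1 horizontal
    - H2 horizontal
  Amacrine cells:
    - AC GABA 1
    - AC GABA 2
    - AC GABA 3
    - AC GABA 4
    - AC GABA 5
    - AC glycinergic 1
    - AC glycinergic 2
    - AC glycinergic 3
    - AC glycinergic 4
    - AII amacrine
    - Starburst amacrine
  Bipolar Cells:
    - DB1 bipolar
    - DB2 bipolar
    - DB3a bipolar
    - DB3b bipolar
    - DB4a bipolar
    - DB4b bipolar
    - DB5 bipolar
    - DB6 bipolar
    - Flat midget bipolar
    - Invaginating midget bipolar
    - Blue bipolar
    - Rod bipolar
  Ganglion cells:
    - ON midget ganglion
    - OFF midget ganglion
    - ON parasol ganglion
    - OFF parasol ganglion
    - Small bistratified ganglion
    - Large bistratified ganglion
    - Melanopsin ganglion
    - ON diffuse ganglion
    - OFF diffuse ganglion
  Muller cells:
    - Muller glia
  Astrocytes:
    - Astrocytes
  Glial cells:
    - Glial cells
  Choroidal melanocyte:
    - Choroidal melanocyte
  Microglial:
    - Microglia 1
    - Microglia 2
  Monocytes:
    - Monocytes
  NK cells:
    - NK cells
  T cells:
    - T cells
  Mast cells:
    - Mast cells
  Pericytes:
    - Pericytes
  Fibroblasts:
    - Fibroblasts
  Vascular endothelial cells:
    - Arterial endothelium
    - Venous endothelium
    - Capillary endothelium
broader_groups:
  Rods+Cones:
    - Rods
    - Cones
  Rods+Cones+RPE:
    - Rods
    - Cones
    - RPE
  Endothelial cell:
    - Pericytes
    - Fibroblasts
    - Vascular endothelial cells
  Immune cells:
    - NK cells
    - T cells
    - Mast cells
  Glial cells (broader):
    - Astrocytes
    - Glial cells
    - Microglial
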