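# Series link for the tumor-growth-with-angiogenesis use case, in the
# constrained Manchester dialect.  Individual ids keep the published
# spellings (including the inconsistent capitalization of the file-root id
# and the transposed "Agniogenesis" in the time-step id).  The extent and
# pixel-distance-scale quality individuals carry the published values:
# a 180 x 180 x 180 voxel lattice with a 4.44 micrometer voxel edge.

Individual: TumorGrowthWithAngiogenesis
    Types: CBO:System
    Facts: has_Quality use_case_1_extent,
           has_Quality systemPix2DistSc,
           has_Quality TumorGrowthWithAngiogenesis_VTK_InitialFile,
           has_Quality TumorGrowthWithAgniogenesis_VTK_FileTimeStep,
           has_Quality tumorGrowthWithAngiogenesis_VTK_FileRoot

Individual: use_case_1_extent
    Types: CBO:DiscreteExtent
    Facts: CBO:hasStringValue "180 180 180"

Individual: systemPix2DistSc
    Types: CBO:SystemPixelDistanceScale
    Facts: CBO:hasFloatValue "4.44", CBO:hasUnit "UO:micrometer"

Individual: tumorGrowthWithAngiogenesis_VTK_FileRoot
    Types: CBO:VTK_FileRoot
    Facts: hasStringValue "use_case_1"

Individual: TumorGrowthWithAngiogenesis_VTK_InitialFile
    Types: CBO:VTK_InitialCondition
    Facts: hasStringValue "use_case_1_0000000000.vtk"

Individual: TumorGrowthWithAgniogenesis_VTK_FileTimeStep
    Types: CBO:VTK_FileTimeStep
    Facts: CBO:hasFloatValue "1", CBO:hasUnit "minute"
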