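alias,parent,dims,method,sign,args
Tcell,root,CD3|CD19,quadrant,+-,
Bcell,root,CD3|CD19,quadrant,-+,
NK,root,CD16|CD56,quadrant,++,
mono,root,CD14|CD20,quadrant,+-,
lin_neg,root,,boolean,,expr=!Tcell&!Bcell&!NK&!mono
dc,lin_neg,CD14|HLA-DR,quadrant,-+,
CD4,Tcell,CD4|CD8,quadrant,+-,
CD8,Tcell,CD4|CD8,quadrant,-+,
tsub,Tcell,,kmeans_subsets,,"markers=CCR7,CD45RA,CD28;parents=CD4,CD8"
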