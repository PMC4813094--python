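zone,region,n_clusters,n_examined,n_wasted
North East,Bari,9,756,174
North East,Mudug,61,6188,1055
North East,Nugaal,24,1673,322
North West,Awdal,26,862,177
North West,Sanaag,14,412,97
North West,Sool,3,142,24
North West,Togdheer,12,673,124
North West,Woqooyi Galbeed,23,2465,480
South Central,Bakool,75,3534,1330
South Central,Banadir,1,51,11
South Central,Bay,98,5568,1798
South Central,Galgaduud,77,5831,879
South Central,Gedo,111,6985,2616
South Central,Hiraan,142,10743,2085
South Central,Juba Dhexe,77,5253,960
South Central,Juba Hoose,71,5560,926
South Central,Shebelle Dhexe,101,7650,1322
South Central,Shebelle Hoose,141,9432,1355
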