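{"signature":[1,1,1,2],"reduced":[["m",0],["m",1],["m",2],["u1",3],["u2",3]],"provenance":"numeric-interpolation","max_degree":2,"polys":[[[1,1,[0]],[-1,2,[2]],[-3,2,[0,4]],[-1,1,[1,3]],[-1,2,[1,4]],[1,2,[2,3]],[1,1,[2,4]]],[[1,1,[1]],[-1,1,[2]],[-1,1,[1,3]],[-1,2,[1,4]],[1,2,[2,3]],[1,1,[2,4]]],[[1,1,[0,3]],[-1,1,[0,4]],[-1,1,[1,3]],[-1,2,[1,4]],[1,2,[2,3]],[1,1,[2,4]]],[[1,1,[0]],[-1,2,[1]],[-3,2,[0,3]],[1,1,[1,3]],[1,2,[1,4]],[-1,2,[2,3]],[-1,1,[2,4]]]],"checksum":"1ce7fe31aa1b0e0c8ff08cced84806ce994c5a516f6c9a3dcdb05472006d8120"}
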