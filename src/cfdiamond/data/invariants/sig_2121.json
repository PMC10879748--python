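{"signature":[2,1,2,1],"reduced":[["m",0],["m",1],["u1",2],["u2",2],["m",3],["m",4],["m",5],["m",6],["m",7]],"provenance":"numeric-interpolation","max_degree":2,"polys":[[[1,1,[0]],[1,1,[1]],[-1,1,[4]],[-2,1,[0,2]],[-1,1,[0,3]]]],"checksum":"a2b8911c09dcc2eecabcd1f51704c22d62b61ffe4b55646ebe046b146a22086a"}
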